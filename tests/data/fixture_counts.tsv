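gene	wtO12_r1	wtO12_r2	wtO14_r1	wtO14_r2	wtO16_r1	wtO16_r2	kitO12_r1	kitO12_r2	kitO14_r1	kitO14_r2	kitO16_r1	kitO16_r2	testis14_r1	testis14_r2
GeneA	10	10	100	100	100	100	10	10	10	10	10	10	5	5
GeneB	5	5	5	5	5	5	5	5	5	5	5	5	5	5
GeneC	50	50	50	50	50	50	50	50	50	50	50	50	5	5
GeneD	10	10	100	100	100	100	10	10	10	10	10	10	100	100
GeneE	100	100	100	100	100	100	10	10	10	10	10	10	5	5
Rec8	20	20	80	80	80	80	40	40	40	40	40	40	4	4
GeneG	10	10	10	10	100	100	10	10	10	10	10	10	2	2
GeneH	10	10	100	100	100	100	40	40	60	60	10	10	5	5
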