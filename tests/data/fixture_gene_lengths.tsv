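gene	length_bp
GeneA	1000
GeneB	1000
GeneC	1000
GeneD	1000
GeneE	1000
Rec8	1000
GeneG	1000
GeneH	1000
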