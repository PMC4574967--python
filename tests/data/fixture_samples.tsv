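sample_id	tissue	genotype	age	replicate	library_size
wtO12_r1	ovary	wildtype	12.5	r1	1000000
wtO12_r2	ovary	wildtype	12.5	r2	1000000
wtO14_r1	ovary	wildtype	14.5	r1	1000000
wtO14_r2	ovary	wildtype	14.5	r2	1000000
wtO16_r1	ovary	wildtype	16.5	r1	1000000
wtO16_r2	ovary	wildtype	16.5	r2	1000000
kitO12_r1	ovary	kit_null	12.5	r1	1000000
kitO12_r2	ovary	kit_null	12.5	r2	1000000
kitO14_r1	ovary	kit_null	14.5	r1	1000000
kitO14_r2	ovary	kit_null	14.5	r2	1000000
kitO16_r1	ovary	kit_null	16.5	r1	1000000
kitO16_r2	ovary	kit_null	16.5	r2	1000000
testis14_r1	testis	wildtype	14.5	r1	1000000
testis14_r2	testis	wildtype	14.5	r2	1000000
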