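sample	patient	specimen	n_snvs	printed_mutations_per_mb	exonic	nonsynonymous	intronic	shared
1084_P0	1084	plasma	4056	1.35	37	25	854	228
1084_T0	1084	tumour	6070	2.02	77	59	1950	228
1249_P0	1249	plasma	4142	1.38	39	27	897	387
1249_T0	1249	tumour	1120	0.37	13	10	288	387
1494_P0	1494	plasma	3433	1.14	22	11	783	262
1494_T0	1494	tumour	1271	0.42	18	11	392	262
1524_P0	1524	plasma	4771	1.59	39	23	1090	281
1524_T0	1524	tumour	2841	0.95	37	23	840	281
065_P0	065	plasma	3857	1.29	38	24	897	
098_P0	098	plasma	5637	1.88	47	28	1356	
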