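pair	n_flanking	kaks_mean	kaks_sd	ks_mean	ks_sd	date_mya
PtrWRKY41/53	21	0.2956	0.1619	0.2958	0.0823	16.2512
PtrWRKY62/89	18	0.2260	0.1143	0.3045	0.0941	16.7297
PtrWRKY64/63	15	0.3577	0.1307	0.2857	0.0777	15.6974
PtrWRKY64/53	7	0.2751	0.1394	1.0270	0.6001	56.4264
PtrWRKY63/53	6	0.2071	0.1755	1.1829	0.7230	64.9923
PtrWRKY41/64	5	0.2130	0.1245	1.2803	0.3083	70.3443
PtrWRKY41/63	5	0.2540	0.0519	1.2109	0.0761	66.5330
PtrWRKY90/55	5	0.3287	0.0633	0.2635	0.0936	14.4753
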