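parameter	target	valid_n	spearman_r	t_printed	p_printed
CDR	C1QBP	82	0.082	0.732	0.466
CDR	PNMA2	82	-0.286	-2.673	0.009
CDR	TARS	82	0.098	0.884	0.379
CDR	HSPD1	82	-0.284	-2.648	0.010
MD	C1QBP	55	0.113	0.826	0.413
MD	PNMA2	55	-0.155	-1.140	0.260
MD	TARS	55	0.335	2.586	0.012
MD	HSPD1	55	-0.421	-3.376	0.001
IOP	C1QBP	114	-0.120	-1.279	0.203
IOP	PNMA2	114	0.091	0.964	0.337
IOP	TARS	114	0.085	0.905	0.367
IOP	HSPD1	114	0.037	0.396	0.693
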