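accession	entry_name	gene	neg_log10_p	log2_difference
P62805	H4_HUMAN	HIST1H4A	2.028	-3.428
Q08J23	NSUN2_HUMAN	NSUN2	6.063	-3.172
P13010	XRCC5_HUMAN	XRCC5	1.496	-2.564
P12814	ACTN1_HUMAN	ACTN1	3.484	-2.437
P26639	SYTC_HUMAN	TARS	2.706	-2.362
Q6UVK1	CSPG4_HUMAN	CSPG4	2.490	1.816
Q02878	RL6_HUMAN	RPL6	2.340	1.819
Q14566	MCM6_HUMAN	MCM6	2.164	1.950
Q96AB3	ISOC2_HUMAN	ISOC2	3.856	2.043
Q9NTK5	OLA1_HUMAN	OLA1	1.786	2.053
Q00005	2ABB_HUMAN	PPP2R2B	3.909	2.226
P10809	CH60_HUMAN	HSPD1	1.705	2.305
P42704	LPPRC_HUMAN	LRPPRC	2.342	2.350
O00159	MYO1C_HUMAN	MYO1C	5.121	2.368
P63104	1433Z_HUMAN	YWHAZ	1.907	2.527
P46940	IQGA1_HUMAN	IQGAP1	3.117	2.680
Q07021	C1QBP_HUMAN	C1QBP	2.513	3.536
Q9ULC4	MCTS1_HUMAN	MCTS1	6.556	3.560
P27708	PYR1_HUMAN	CAD	3.204	3.754
P63241	IF5A1_HUMAN	EIF5A	2.437	4.028
Q9UL42	PNMA2_HUMAN	PNMA2	6.185	4.521
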