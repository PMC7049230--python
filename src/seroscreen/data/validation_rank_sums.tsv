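target	n_poag	n_ctrl	rank_sum_poag	rank_sum_ctrl	u_printed	z_printed	p_printed	z_adjusted_printed
PPP2R2B	120	120	14078	14842	6818	-0.710	0.477	-0.712
TARS	120	120	16741	12179	4919	4.242	0.000	4.258
C1QBP	120	120	15714	13206	5946	2.332	0.020	2.333
PNMA2	120	120	16032	12888	5628	2.923	0.003	2.930
MCTS1	120	120	15015	13905	6645	1.032	0.302	1.034
HSPD1	120	120	16793	12127	4867	4.338	0.000	4.350
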