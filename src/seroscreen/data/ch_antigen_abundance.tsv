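entry_name	accession	ibaq_pct
FLNA	P21333	1.24
TBB6	Q9BUF5	6.51
SYEP	P07814	1.15
SET	Q01105	8.23
TBB4B	P68371	5.88
SYIC	P41252	0.99
FAS	P49327	0.44
TERA	P55072	1.14
H4	P62805	14.39
XRCC5	P13010	2.28
RS2	P15880	3.09
H2B1L	Q99880	9.69
HNRPF	P52597	4.65
RS16	P62249	4.6
SYTC	P26639	1.77
PLPHP	O94903	1.81
HS90B	P08238	1.41
ATPA	P25705	1.56
SERPH	P50454	1.6
NPM	P06748	3.29
MCM7	P33993	0.55
CCD47	Q96A33	2.03
ADT2	P05141	1.69
SYRC	P54136	0.74
IF4A1	P60842	1.69
IQGA1	P46940	0.1
HNRPK	P61978	1.01
EIF3L	Q9Y262	0.54
SYK	Q15046	0.5
SYDC	P14868	0.66
SRP68	Q9UHB9	0.51
TBA1A	Q71U36	1.07
RS24	P62847	2.63
RL15	P61313	1.3
EIF3E	P60228	0.45
EIF3F	O00303	0.76
SYQ	P47897	0.36
TCPZ	P40227	0.47
MYO1C	O00159	0.05
EIF3A	Q14152	0.16
DEST	P60981	1.63
EIF3B	P55884	0.26
SYMC	P56192	0.33
NSUN2	Q08J23	0.43
COPG1	Q9Y678	0.2
MCM3	P25205	0.13
PSMD2	Q13200	0.12
OLA1	Q9NTK5	0.19
RS5	P46782	0.9
ACTN1	P12814	0.27
PYRG1	P17812	0.19
PPIL4	Q8WUA2	0.34
NU160	Q12769	0.06
P5CS	P54886	0.14
TKT	P29401	0.21
DCTN1	Q14203	0.08
CLH1	Q00610	0.07
PRP8	Q6P2Q9	0.03
DX39A	O00148	0.31
TIM50	Q3ZCQ8	0.4
CPSF7	Q8N684	0.25
SPT5H	O00267	0.07
IMB1	Q14974	0.06
RT35	P82673	0.17
TGFI1	O43294	0.11
DDX46	Q7L014	0.05
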