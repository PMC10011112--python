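# Transcribed numerator/denominator counts and printed percentages from the
# source study's cohort tables (overall incidence, Table 1 complication rates
# by sepsis status, Table 3 rates by follow-up period and GRS group, White
# subjects).  Counts only; used to verify that every printed percentage is
# reproduced by numerator/denominator at printed precision.
table	outcome	row	period	numerator	denominator	printed
overall	sepsis	cohort	entire	10757	483177	2.23
table1	MI	sepsis_yes	entire	506	10757	4.7
table1	MI	sepsis_no	entire	15012	472420	3.18
table1	IS	sepsis_yes	entire	271	10757	2.52
table1	IS	sepsis_no	entire	6543	472420	1.38
table1	VTE	sepsis_yes	entire	638	10757	5.93
table1	VTE	sepsis_no	entire	8102	472420	1.71
table1	composite	sepsis_yes	entire	1330	10757	12.36
table1	composite	sepsis_no	entire	28052	472420	5.94
table3	MI	sepsis_no	subjects	444311	454493	97.76
table3	MI	sepsis_no	entire	14063	444311	3.17
table3	MI	sepsis_no	short	48	444311	0.01
table3	MI	sepsis_no	mid	1234	444192	0.28
table3	MI	sepsis_no	long	12776	442958	2.88
table3	MI	sepsis_yes	subjects	10182	454493	2.24
table3	MI	sepsis_yes	entire	478	10182	4.69
table3	MI	sepsis_yes	short	179	10182	1.76
table3	MI	sepsis_yes	mid	158	9994	1.58
table3	MI	sepsis_yes	long	141	9836	1.43
table3	MI	grs_low	subjects	630	9827	6.41
table3	MI	grs_low	entire	22	630	3.49
table3	MI	grs_low	short	4	630	0.63
table3	MI	grs_low	mid	7	626	1.12
table3	MI	grs_low	long	11	619	1.78
table3	MI	grs_intermediate	subjects	9042	9827	92.01
table3	MI	grs_intermediate	entire	428	9042	4.73
table3	MI	grs_intermediate	short	167	9042	1.85
table3	MI	grs_intermediate	mid	142	8866	1.6
table3	MI	grs_intermediate	long	119	8724	1.36
table3	MI	grs_high	subjects	155	9827	1.58
table3	MI	grs_high	entire	14	155	9.03
table3	MI	grs_high	short	3	155	1.94
table3	MI	grs_high	mid	4	152	2.63
table3	MI	grs_high	long	7	148	4.73
table3	IS	sepsis_no	entire	6202	444311	1.4
table3	IS	sepsis_no	short	20	444311	0
table3	IS	sepsis_no	mid	524	444221	0.12
table3	IS	sepsis_no	long	5658	443697	1.28
table3	IS	sepsis_yes	entire	257	10182	2.52
table3	IS	sepsis_yes	short	108	10182	1.06
table3	IS	sepsis_yes	mid	91	10065	0.9
table3	IS	sepsis_yes	long	58	9974	0.58
table3	IS	grs_low	subjects	320	9452	3.39
table3	IS	grs_low	entire	8	320	2.5
table3	IS	grs_low	short	3	320	0.94
table3	IS	grs_low	mid	4	317	1.26
table3	IS	grs_low	long	1	313	0.32
table3	IS	grs_intermediate	subjects	8994	9452	95.15
table3	IS	grs_intermediate	entire	226	8994	2.51
table3	IS	grs_intermediate	short	94	8994	1.05
table3	IS	grs_intermediate	mid	81	8892	0.91
table3	IS	grs_intermediate	long	51	8811	0.58
table3	IS	grs_high	subjects	138	9452	1.46
table3	IS	grs_high	entire	6	138	4.35
table3	IS	grs_high	short	2	138	1.45
table3	IS	grs_high	mid	1	136	0.74
table3	IS	grs_high	long	3	135	2.22
table3	VTE	sepsis_no	entire	7753	444311	1.74
table3	VTE	sepsis_no	short	19	444311	0
table3	VTE	sepsis_no	mid	723	444221	0.16
table3	VTE	sepsis_no	long	7007	443498	1.58
table3	VTE	sepsis_yes	entire	604	10182	5.93
table3	VTE	sepsis_yes	short	290	10182	2.85
table3	VTE	sepsis_yes	mid	212	9883	2.15
table3	VTE	sepsis_yes	long	102	9671	1.05
table3	VTE	grs_low	subjects	2159	9713	22.23
table3	VTE	grs_low	entire	110	2159	5.09
table3	VTE	grs_low	short	60	2159	2.78
table3	VTE	grs_low	mid	26	2097	1.24
table3	VTE	grs_low	long	24	2071	1.16
table3	VTE	grs_intermediate	subjects	6982	9713	71.88
table3	VTE	grs_intermediate	entire	405	6982	5.8
table3	VTE	grs_intermediate	short	188	6982	2.69
table3	VTE	grs_intermediate	mid	148	6787	2.18
table3	VTE	grs_intermediate	long	69	6639	1.04
table3	VTE	grs_high	subjects	572	9713	5.89
table3	VTE	grs_high	entire	52	572	9.09
table3	VTE	grs_high	short	28	572	4.9
table3	VTE	grs_high	mid	17	544	3.12
table3	VTE	grs_high	long	7	527	1.33
table3	composite	sepsis_no	entire	26503	444311	5.96
table3	composite	sepsis_no	short	88	444311	0.02
table3	composite	sepsis_no	mid	2437	444153	0.55
table3	composite	sepsis_no	long	23969	441716	5.43
table3	composite	sepsis_yes	entire	1257	10182	12.35
table3	composite	sepsis_yes	short	563	10182	5.53
table3	composite	sepsis_yes	mid	427	9610	4.44
table3	composite	sepsis_yes	long	267	9183	2.91
table3	composite	all_low	subjects	2555	9846	25.95
table3	composite	all_low	entire	292	2555	11.43
table3	composite	all_low	short	134	2555	5.24
table3	composite	all_low	mid	98	2418	4.05
table3	composite	all_low	long	60	2320	2.59
table3	composite	remaining	subjects	6450	9846	65.51
table3	composite	remaining	entire	791	6450	12.26
table3	composite	remaining	short	352	6450	5.46
table3	composite	remaining	mid	269	6092	4.42
table3	composite	remaining	long	170	5823	2.92
table3	composite	any_high	subjects	841	9846	8.54
table3	composite	any_high	entire	131	841	15.58
table3	composite	any_high	short	59	841	7.02
table3	composite	any_high	mid	40	782	5.12
table3	composite	any_high	long	32	742	4.31
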