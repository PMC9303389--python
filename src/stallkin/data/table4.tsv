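stall_site	supercoil_sign	force_pN	torque_pNnm	rapa_nM	atp_uM	extra_component	stall_cause	mean_lifetime_s	lifetime_se_s	n_events
20	1	0.3	12	0	1000		C-less
20	-1	0.3	-12	0	1000		C-less
20	1	3.0	37	0	1000		C-less	12600	2430	61
20	1	4.0	42	0	1000		C-less	10800	1920	73
20	1	6.0	52	0	1000		C-less	2500	426	64
20	1	0.3	12	100	1000		C-less	983	61.9	289
20	1	0.7	18	100	1000		C-less	542	63.9	112
20	1	1.1	22	100	1000		C-less	365	41.6	150
20	1	1.6	27	100	1000		C-less	223	23.9	248
20	1	2.0	30	100	1000		C-less	181	27.5	87
20	-1	0.3	-12	100	1000		C-less
20	1	0.3	12	500	1000		C-less	965	82.5	212
20	1	0.3	12	10	1000		C-less	1800	144	244
20	1	0.3	12	3	1000		C-less	3270	182	421
20	1	0.3	12	100	400		C-less	1080	97.1	195
20	1	0.3	12	100	200		C-less	1600	163	249
20	1	0.3	12	100	125		C-less	1870	212	135
20	1	0.3	12	100	1000	50 nM GreB	C-less	1730	343	45
20	1	0.3	12	100	1000	50 nM GreB (no UTP or GTP)	C-less	940	205	36
20	1	2.0	30	100	1000		CPD	796	179	37
20	1	2.0	30	100	1000		C-less	181	27.5	87
36	1	2.0	30	100	1000		C-less	328	43.4	85
36	1	2.0	30	100	1000	100 nM RNA-hybridising oligo	C-less	4070	2700	4
83	1	2.0	30	100	1000		CPD	1890	505	24
83	1	2.0	30	100	1000	100 ug/ml RNAse A	CPD	215	45.5	38
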