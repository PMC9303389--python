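greb_nM	atp_mM	utp_uM	gtp_uM	n_initiated	n_removed	percent_removed	mean_lifetime_s	lifetime_se_s
0	1	200	200	74	72	97	983	62
50	1	200	200	87	45	52	1732	343
50	1	0	0	43	36	84	940	205
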