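oligo_nM	n_initiated	n_removed	percent_removed	observation_window	mean_lifetime_s	lifetime_se_s
0	105	85	81	1 h	328	43.4
100	22	4	18	5 h	4070	2700
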