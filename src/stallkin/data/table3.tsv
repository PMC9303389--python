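condition	n_molecules	percent_removed	percent_backtracking	percent_backtracking_to_promoter	mean_lifetime_s	lifetime_se_s	duration_h
Tethered-RNAP stalled at +20 (RapA absent)	6	0					19
Tethered-RNAP stalled at +20 in presence of RapA and ATP	10	80			3060	233	6
Tethered-RNAP stalled hundreds of base-pairs from promoter in presence of RapA and ATP	18	67	67	33	10100	1000	6
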