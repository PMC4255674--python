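replicon	size_bp	gc_percent	gene_count	potential_sites	observed_sites	insertion_density	mean_read_count	median_read_count
Chrom	5057142	61.10	4800	89660	73375	0.82	20.46	13.00
pRL12	870021	61.00	790	14845	13122	0.88	18.57	12.00
pRL11	684202	61.00	644	12456	10964	0.88	19.97	13.00
pRL10	488135	59.60	471	10003	8470	0.85	17.19	10.00
pRL09	352782	61.00	313	6359	5453	0.86	19.65	13.00
pRL08	147463	58.70	142	3118	2702	0.87	17.96	11.00
pRL07	151546	57.60	186	3615	2458	0.68	22.09	12.00
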