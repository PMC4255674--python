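replicon	mapped_reads	ES	GD	NE	GA	NoData
Chrom	1501032	317	272	4176	35	0
pRL12	243699	8	3	774	3	2
pRL11	218944	15	9	614	3	3
pRL10	145621	15	3	447	3	3
pRL09	107144	7	1	305	0	0
pRL08	48512	3	1	137	1	0
pRL07	54287	4	48	124	8	2
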