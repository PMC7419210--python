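species	build	chrom	anchor_start	anchor_end	deletion_kbp	repeat_pct	ltr_pct	line_pct	sine_pct	unique_pct	insertion_kbp	flag
Marmoset	hg38	chr4	160005326	160008761	3.4	99.6	0.8	1.3	17.6	0.03	21.6
Marmoset	hg38	chr20	20011993	20016575	4.6	66.8	4.9	19.3	37.5	33	25.7
Marmoset	hg38	chr11	134267373	134272307	4.9	48	10.3	5.8	26.6	52	243
Marmoset	hg38	chr11	93232994	93232995	0	.	.	.	.	.	148
Marmoset	hg38	chr16	11452411	11525004	72.6	57.6	3.66	14.7	29.3	42.3	21
Marmoset	hg38	chr17_chr13	83228403	19349530	.	.	.	.	.	.	358.5	cytogenetic_rearrangement
Chimpanzee	rheMac8	chr20	15098676	15131780	32.5	65.8	10.4	3.4	15	0.5	69.8
Squirrel monkey	hg38	chr2	100587592	100601735	14.1	69.9	2.6	4.8	35.3	30.1	52.5
Chimpanzee	hg38	chr17	44694772	44700734	5.9	92.7	0	8.3	70.6	7.3	80
Orangutan	hg38	chr13	24407831	24480143	80.1	55.65	2	3.1	22	44.4	140
Orangutan	hg38	chr13	25361286	25366987	5.7	74.1	2.25	5.5	15.2	25.9	90
Gorilla	hg38	chr16	27185611	27191436	5.8	83.7	30	26.3	22.8	16.3	100
Gorilla	hg38	chr16	23303992	23307429	3.4	91.2	0	23.6	71.3	4.2	50
Chimpanzee	hg38	chr16	2782469	2798105	16.1	61.8	17.3	13.4	23.7	38.2	30
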