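cell_line	cancer_type	loh	tai	lst	ploidy	hrd_score	brca_mutation	brca1_methylation_pct
HCC38	BRCA	30	24	71	3.34	73.21	WT	74.33
HCC1806	BRCA	34	23	42	2.29	63.47	WT	1.41
NCI/ADR-RES	OV	32	19	47	2.32	61.99	WT	64.64
HCC1143	BRCA	28	20	67	3.59	59.35	WT	1.26
HCC70	BRCA	29	23	57	3.22	59.13	WT	0.28
MX-1	BRCA	30	21	50	2.72	58.9	BRCA1 c.2679_2682delGAAA p.K893Nfs*106 frameshift 99.84%	2.40
OVCAR4	OV	29	19	55	3.12	54.67	WT	47.56
HCC1428	BRCA	17	17	53	3.62	30.82	WT	0.31
ZR-75-1	BRCA	9	15	40	3.2	14.42	WT	0.17
MDA-MB-453	BRCA	11	16	48	4.17	10.42	WT	0.45
MDA-MB-231	BRCA	11	11	30	2.78	8.9	WT	0.19
MDA-MB-361	BRCA	6	13	46	3.67	8.18	WT	1.91
MDA-MB-415	BRCA	9	13	34	3.09	8.1	WT	0.09
ZR-75-30	BRCA	7	13	41	3.67	4.1	WT	3.77
HS-578T	BRCA	10	7	16	2.47	-5.33	WT	0.22
IGR-OV1	OV	7	0	7	1.85	-14.73	BRCA1 c.1961delA p.K654Sfs*47 frameshift 50.07%	0.15
A2780	OV	3	3	4	2.01	-21.19	WT	0.69
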