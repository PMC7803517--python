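gene_id	gene_name	keloid_day0	keloid_day42	keloid_log2fc	keloid_padj	control_day0	control_day42	control_log2fc	control_padj
ENSG00000231607	DLEU2	306.79	641.38	1.06	1.33e-17	74.88	66.26	-0.18	1.00
ENSG00000272657	AP000317.2	75.61	183.43	1.28	3.53e-17	66.42	119.35	0.85	7.08e-3
ENSG00000272734	ADIRF-AS1	1350.45	552.62	-1.29	2.46e-29	1251.46	646.56	-0.95	1.24e-5
ENSG00000272686	AC006333.2	82.88	39.50	-1.07	8.29e-9	70.48	41.97	-0.75	1.46e-2
ENSG00000272084	AL137127.1	661.42	240.08	-1.46	2.66e-18	407.22	223.42	-0.87	7.60e-5
ENSG00000233008	LINC01725	257.15	121.20	-1.09	1.87e-13	211.00	134.79	-0.65	4.60e-2
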