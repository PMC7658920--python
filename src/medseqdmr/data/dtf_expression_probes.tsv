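# description=Published probe-level mRNA expression summary (Affymetrix Human Genome U133 Plus 2.0) for the genes associated with fold-change >= 1.5 DMRs, over 34 S45F and 45 T41A desmoid tumors; pooled median with interquartile range and two-sided Mann-Whitney p-value between mutation groups.
gene	probe	median	iqr_low	iqr_high	p_value
CCDC6	204716_at	203	126	239	0.034
CCDC6	225010_at	617	554.6	703.4	0.579
FOXK2	242937_at	17	15	21	0.004
FOXK2	242938_s_at	34	32	39	0.384
FOXK2	226224_at	149	141	158	0.373
FOXK2	203064_s_at	112	101	127	0.533
DUX4L6	216472_x_at	11	8	14	0.362
DUX4L6	208201_at	15	11	20	0.510
NLRP4	242334_at	2.7	1.2	4.2	0.149
NOC4L	218860	50	44	55	0.628
PERM1	224501_at	1	1	1	0.415
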