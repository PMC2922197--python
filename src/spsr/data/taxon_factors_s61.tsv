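parent	taxon	n_enzymes	n_tsps	n_hits	factor
	Archaea	543	408	1807	3.33
	Eukaryota	259	150	260	1.00
	Bacteria	7752	8310	98556	12.71
Bacteria	Proteobacteria	4341	3768	34376	7.92
Bacteria	Firmicutes	1561	1130	7457	4.78
Bacteria	Cyanobacteria	328	175	541	1.65
Bacteria	Actinobacteria	494	392	1874	3.79
Bacteria	Tenericutes	193	25	72	0.37
Bacteria	Bacteroidetes	132	103	223	1.69
Bacteria	Spirochaetes	185	71	173	0.94
Bacteria	Thermotogae	81	9	22	0.27
Bacteria	Chlamydiae	114	140	383	3.36
Bacteria	Chlorobi	90	31	79	0.88
Archaea	Crenarchaeota	165	53	158	0.96
Archaea	Euryarchaeota	359	281	932	2.60
Proteobacteria	Gammaproteobacteria	2372	1624	13622	5.74
Proteobacteria	Alphaproteobacteria	870	675	3806	4.37
Proteobacteria	Betaproteobacteria	638	394	1950	3.06
Proteobacteria	Epsilonproteobacteria	223	178	430	1.93
Proteobacteria	Deltaproteobacteria	229	9	19	0.08
Firmicutes	Bacillales	614	327	1811	2.95
Firmicutes	Clostridia	374	142	567	1.52
Firmicutes	Lactobacillales	573	387	2543	4.44
Cyanobacteria	Chroococcales	114	64	184	1.61
Bacteroidetes	Bacteroidia	85	67	138	1.62
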