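ec	read_length	rf	nf	sd
1.1.1	50		0.15	0.014
1.2.1	50		0.28	0.024
2.1.1	50		0.22	0.030
2.3.1	50		0.11	0.023
2.4.1	50		0.16	0.028
2.4.2	50		0.26	0.011
2.5.1	50		0.25	0.011
2.6.1	50		0.17	0.010
2.7.13	50		0.03	0.003
2.7.7	50		0.45	0.022
3.1.1	50		0.08	0.022
3.1.3	50		0.07	0.010
3.2.1	50		0.07	0.017
3.5.1	50		0.15	0.034
3.6.1	50		0.89	0.026
3.6.3	50		0.45	0.064
4.1.1	50		0.25	0.019
4.2.1	50		0.30	0.024
6.1.1	50		1.00	0.000
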