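ec	doublets	triplets	proteins	pct_multiples	s61
6.1.1.1	18	0	474	3.80
6.1.1.2	3	0	125	2.40
6.1.1.3	1	0	616	0.16	x
6.1.1.4	2	0	703	0.28	x
6.1.1.5	10	0	524	1.91	x
6.1.1.6	60	3	527	12.52
6.1.1.7	1	0	628	0.16	x
6.1.1.9	0	0	293	0.00	x
6.1.1.10	2	0	421	0.48	x
6.1.1.11	4	0	735	0.54	x
6.1.1.12	2	0	688	0.29	x
6.1.1.13	68	1	172	40.70
6.1.1.14	276	0	825	33.45
6.1.1.15	10	0	762	1.31	x
6.1.1.16	14	0	691	2.03	x
6.1.1.17	114	0	808	14.11
6.1.1.18	0	0	139	0.00	x
6.1.1.19	4	0	675	0.59	x
6.1.1.20	251	0	877	28.62
6.1.1.21	6	0	627	0.96	x
6.1.1.22	1	0	256	0.39	x
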