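name	transcript_bp	length_aa	mol_wt_kda	pI	gravy	aliphatic_index	instability_index	total_atoms	avg_residue_wt	net_charge
BoCNGC1	2115	704	81.33	9.18	-0.212	90.88	47.95	11473	115.5	22
BoCNGC2	2112	703	81.09	9.78	-0.139	87.92	37.21	11462	115.3	33.5
BoCNGC3	1950	649	75.08	9.89	-0.023	99.14	39.96	10654	115.7	39
BoCNGC4	2214	737	84.58	9.74	-0.177	92.51	49.74	11989	114.8	31
BoCNGC5	2238	745	85.27	9.85	-0.193	89.69	50.69	12073	114.5	36.5
BoCNGC6	2226	741	84.49	9.53	-0.169	91.61	48.38	11959	114.0	25.5
BoCNGC7	2166	721	82.52	9.35	-0.122	89.28	50.45	11653	114.4	26
BoCNGC8	2226	741	85.08	9.17	-0.266	86.22	51.02	11997	114.8	19.5
BoCNGC9	2055	684	79.43	10.08	-0.11	91.23	49.17	11253	116.1	38
BoCNGC10	2184	727	84.17	8.8	-0.187	91.21	45.73	11876	115.8	17
BoCNGC11	2187	728	83.84	9.12	-0.096	93.48	46.34	11863	115.2	21.5
BoCNGC12	2202	733	84.52	9.29	-0.13	94.69	48.3	11982	115.3	23
BoCNGC13	2106	701	79.63	8.23	-0.149	84.86	45.08	11147	113.6	12
BoCNGC14	2121	706	81.58	8.36	-0.247	86.08	52.08	11403	115.6	15
BoCNGC15	2088	695	80.24	8.25	-0.176	91.12	55.15	11285	115.5	13.5
BoCNGC16	2097	698	80.78	8.19	-0.192	90.6	55.83	11357	115.7	12
BoCNGC17	2151	716	81.93	9.81	0.018	94.61	54.04	11569	114.4	38.5
BoCNGC18	2160	674	76.69	8.38	-0.121	89.96	50.37	10797	114.0	13.5
BoCNGC19	1677	558	63.94	7.26	-0.187	87.63	45.22	8953	114.6	5
BoCNGC20	2262	753	85.98	9.8	-0.075	92.19	52.29	12121	114.2	32
BoCNGC21	2280	759	86.21	9.81	-0.067	90.59	47.96	12147	113.6	32.5
BoCNGC22	2205	734	82.99	9.2	0.033	93.37	47.16	11692	113.1	28
BoCNGC23	2370	789	89.00	10.18	-0.055	95.64	46.62	12604	112.8	42
BoCNGC24	2232	743	85.06	10.06	-0.103	90.93	53.01	11990	114.5	37
BoCNGC25	2346	781	89.78	10.11	-0.176	90.73	47.88	12686	115.0	34.5
BoCNGC26	2235	744	85.72	9.3	-0.231	85.44	53.09	12036	115.2	21.5
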