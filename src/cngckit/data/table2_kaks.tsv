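at_gene	bo_gene	ka	ks	kaks
AtCNGC13	BoCNGC1	0.137	0.032	4.303387233
AtCNGC3	BoCNGC2	0.147	0.029	5.117236906
AtCNGC6	BoCNGC4	0.136	0.052	2.615208996
AtCNGC6	BoCNGC5	0.167	0.048	3.468082016
AtCNGC9	BoCNGC6	0.188	0.024	7.768521972
AtCNGC5	BoCNGC7	0.124	0.040	3.098687155
AtCNGC7	BoCNGC8	0.111	0.033	3.40004813
AtCNGC15	BoCNGC9	0.147	0.060	2.456018066
AtCNGC17	BoCNGC10	0.113	0.034	3.357834045
AtCNGC14	BoCNGC11	0.133	0.031	4.245278743
AtCNGC14	BoCNGC12	0.145	0.040	3.651430365
AtCNGC18	BoCNGC13	0.094	0.048	1.949453718
AtCNGC16	BoCNGC14	0.111	0.066	1.676233706
AtCNGC4	BoCNGC15	0.101	0.025	4.039237878
AtCNGC4	BoCNGC16	0.103	0.034	3.056103924
AtCNGC2	BoCNGC17	0.118	0.029	4.091069466
AtCNGC19	BoCNGC18	0.246	0.126	1.950211367
AtCNGC20	BoCNGC19	0.202	0.178	1.133449904
AtCNGC20	BoCNGC20	0.136	0.049	2.79662626
AtCNGC20	BoCNGC21	0.099	0.041	2.44174101
AtCNGC19	BoCNGC22	0.202	0.119931313	1.680530313
AtCNGC19	BoCNGC24	0.146	0.081	1.792823624
AtCNGC19	BoCNGC25	0.146	0.081	1.792823624
AtCNGC20	BoCNGC26	0.131	0.125	1.054276842
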