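mirna_id	target_id	expectation	upe	mirna_3to5	target_5to3	target_start	target_end	inhibition	multiplicity	typeset_ambiguous
bol-miR5021a/j	BoCNGC4	2.5	16.412	AGAAGAAGAAGAAGAAGAAU	CUUUCCUCUUCUUCUUCUUA	60	79	Cleavage	1	0
bol-miR838d	BoCNGC5	2.5	15.037	CUUGUUCUUCUUCUUCUUCU	GAAGAGGAAGAAGAGGAGGA	2884	2903	Cleavage	1	0
bol-miR838d	BoCNGC6	2.0	15.121	CUUGUUCUUCUUCUUCUUCU	GAAGAAGAGGAGGAAGAAGA	2593	2612	Cleavage	1	0
bol-miR414b	BoCNGC8	3.0	16.071	ACUUCUACUUCUACUUCUACU	UGAAGAUGAGUAUGAUGAUGA	2589	2609	Translation	1	1
bol-miR838d	BoCNGC10	2.0	8.16	CACUUGUUCUUCUUCUUCUUCU	GUGAUGAAGAAGAAGAAGAAGA	3520	3541	Cleavage	1	0
bol-miR4234	BoCNGC12	3.0	15.182	UGACGGUUGAUCAAAAUUCAAC	AUUUUCAAUUGGUUUUGAGUUG	2630	2651	Cleavage	1	1
bol-miR838d	BoCNGC15	1.5	6.045	CUUGUUCUUCUUCUUCUUCU	GAAGAAGAGGAAGAAGAAGA	103	122	Cleavage	2	0
bol-miR838d	BoCNGC15	2.5	8.952	ACUUGUUCUUCUUCUUCUUCU	UGAGAAAGAUGAAGAAGAAGA	135	155	Cleavage	2	0
bol-miR838d	BoCNGC16	3.0	6.192	CUUGUUCUUCUUCUUCUUCU	GAAGAGGAGGACGAAGAAGA	94	113	Translation	2	0
bol-miR838d	BoCNGC16	1.5	2.883	CUUGUUCUUCUUCUUCUUCU	GAACAAGAGGAAGAGGAGGA	124	143	Cleavage	2	0
bol-miR_new2	BoCNGC26	3.0	11.462	UGGGAUUUAGUAUUUAGGAU	ACCUGGAAUCAUAAAUCCUC	639	658	Cleavage	1	0
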