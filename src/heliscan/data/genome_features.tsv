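group	genome	size_mb	helitron_count	density	dataset
Osa_japonica	Oryza sativa japonica IRGSP v7_JGI	380	2980	7.8421	train
Osa_japonica	Oryza sativa japonica Syngenta	399	3015	7.5564	train
Osa_indica	Oryza sativa indica PA64s	389	2863	7.3599	train
Osa_indica	Oryza sativa indica 93-11	431	3120	7.239	train
Ath	A. thaliana Col-0	121	665	5.4959	train
Ath	A. thaliana Can-0	119.3	590	4.9455	train
Ath	A. thaliana Zu-0	119.7	590	4.929	train
Ath	A. thaliana Po-0	120.5	593	4.9212	train
Ath	A. thaliana Hi-0	120.3	592	4.921	train
Ath	A. thaliana Oy-0	119.5	575	4.8117	train
Ath	A. thaliana Wu-0	119.7	572	4.7786	train
Ath	A. thaliana Sf-2	119.6	567	4.7408	train
Ath	A. thaliana Ct-1	119.6	567	4.7408	train
Ath	A. thaliana Mt-0	119.5	565	4.728	train
Ath	A. thaliana Edi-0	119.8	564	4.7078	train
Ath	A. thaliana Tsu-0	119.6	559	4.6739	train
Ath	A. thaliana Bur-0	119.7	556	4.6449	train
Ath	A. thaliana Rsch-4	119.8	554	4.6244	train
Ath	A. thaliana Ler-0	119.7	552	4.6115	train
Ath	A. thaliana Ws-0	119.8	547	4.5659	train
Ath	A. thaliana Wil-2	119.5	543	4.5439	train
Ath	A. thaliana Kn-0	119.7	542	4.528	train
Tsa	Eutrema salsugineum v1.0	246.2	1060	4.3054	train
Tsa	Thellungiella salsuginea v2	233.7	1032	4.4159	train
Tpa	Thellungiella parvula v8	123.6	202	1.6343	train
Tpa	Schrenkiella parvula	140	223	1.5929	train
Bol	Brassica oleracea A2 v1.1	391	5392	13.7903	train
Bol	Brassica oleracea TO1000 v2.1	498	6979	14.0141	train
Zma	Zm B73 V4.0	2134	8274	3.8765	train
Zma	Zm CML247 V1.1	2197	8791	3.9996	train
Zma	Zm EP1 V1.0	2455	8481	3.4542	train
Zma	Zm F7 V1.0	2392	8602	3.5949	train
Zma	Zm Mo17 V1.0	2182	8602	3.9412	train
Zma	Zm W22 V2.0	2133	8132	3.8109	train
Ath	Denovo_genome_L	121.1	640	5.2849	denovo
Ath	Denovo_genome_X	120.2	643	5.3494	denovo
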