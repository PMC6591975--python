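rank	accession	country	origin	stock	unique_loc	size_mb	helitron_count	density	flowering_time
1	Col-0	USA	Columbia	CS22625	1	121	665	5.4959	intermediate
2	Can-0	Spain	Canary Islands	CS6660	14	119.3	590	4.9455	late
3	Zu-0	Switzerland	Zurich	CS6902	8	119.7	590	4.9290	late
4	Po-0	Germany	Poppelsdorf	CS6839	3	120.5	593	4.9212	intermediate
5	Hi-0	Netherlands	Hilversum	CS6736	3	120.3	592	4.9210	intermediate
6	Oy-0	Norway	Oystese	CS6824	5	119.5	575	4.8117	intermediate
7	Wu-0	Germany	Wurzburg	CS6897	4	119.7	572	4.7786	intermediate
8	Sf-2	Spain	San Feliu	CS6857	11	119.6	567	4.7408	late
9	Ct-1	Italy	Catania	CS6674	5	119.6	567	4.7408	intermediate
10	Mt-0	Libya	Martuba/Cyrenaika	CS1380	4	119.5	565	4.7280	intermediate
11	Edi-0	UK	Edinburgh	CS6688	10	119.8	564	4.7078	late
12	Tsu-0	Japan	Tsushima	CS6874	5	119.6	559	4.6739	intermediate
13	Bur-0	Ireland	Burren	CS6643	6	119.7	556	4.6449	intermediate
14	Rsch-4	Russia	Rschew/Starize	CS6850	3	119.8	554	4.6244	intermediate
15	Ler-0	Poland	Ler	CS20	7	119.7	552	4.6115	intermediate
16	Ws-0	Russia	Wassilewskija	CS6891	9	119.8	547	4.5659	late
17	Wil-2	Russia	Wilna/Litvanian	CS6889	5	119.5	543	4.5439	intermediate
18	Kn-0	Lithuania	Kaunas	CS6762	6	119.7	542	4.5280	intermediate
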