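# Maruca vitrata mitochondrial cistron expression profile from 7,608 raw EST
# reads scaffolded to 10 assembled contigs (= predicted mature cistrons).
# `proportion_pct` is the share of the whole pooled EST library (%), whose
# total size was not published (~13,300 reads implied); only ratios of
# proportions are meaningful. For two rows (MvMtD_02, MvMtD_03) the
# published total_nt does not equal mean_depth * length; all values verbatim.
cistron_id	genes	length	total_nt	mean_depth	read_count	proportion_pct
MvMtD_01	nd2	1033	7829	7.58	24	0.2
MvMtD_02	cox1	1532	265789	290.16	916	6.9
MvMtD_03	cox2	713	239189	300.49	796	6.0
MvMtD_04	atp8,atp6,cox3	2049	171490	83.69	558	4.2
MvMtD_05	nd5	1736	27891	16.07	81	0.6
MvMtD_06	nd4,nd4L	1640	89043	54.29	297	2.2
MvMtD_07	nd6,cytb	1768	117208	66.29	359	2.7
MvMtD_08	nd1	1022	86645	84.48	278	2.1
MvMtD_09	rrnL	1408	1053548	748.29	4288	32.1
MvMtD_10	rrnS	456	2870	6.29	11	0.1
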