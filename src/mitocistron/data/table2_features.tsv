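# Maruca vitrata mitochondrial gene annotation (GenBank HZ751150).
# Coordinates are printed in transcription orientation: L-strand rows usually
# have start5 > stop3. `length` is the declared length as published; it
# disagrees with the coordinate span by 2 for every descending L-strand row.
# `anticodon` holds the published codon-family tag of each tRNA.
name	ftype	strand	start5	stop3	length	start_codon	stop_codon	anticodon
nd2	PCG	H	1	999	999	TTA	TAA	.
trnW	tRNA	H	1007	1074	68	.	.	UGR
trnC	tRNA	H	1068	1131	64	.	.	UGY
trnY	tRNA	L	1199	1137	61	.	.	UAY
cox1	PCG	H	1207	2739	1533	CGA	TAA	.
trnL-uur	tRNA	H	2735	2801	67	.	.	UUR
cox2	PCG	H	2802	3486	685	ATG	T	.
trnK	tRNA	H	3484	3554	71	.	.	AAR
trnD	tRNA	L	3557	3624	68	.	.	GAY
atp8	PCG	H	3624	3785	162	ATT	TAA	.
atp6	PCG	H	3779	4453	675	ATG	TAA	.
cox3	PCG	H	4461	5249	789	ATG	TAA	.
trnG	tRNA	H	5252	5317	66	.	.	GGN
nd3	PCG	H	5318	5671	354	ATT	TAA	.
trnA	tRNA	H	5673	5738	66	.	.	GCN
trnR	tRNA	H	5737	5802	66	.	.	CGN
trnN	tRNA	H	5801	5866	66	.	.	AAY
trnS-agn	tRNA	H	5869	5936	68	.	.	AGN
trnE	tRNA	H	5937	6001	65	.	.	GAR
trnF	tRNA	L	6069	6004	64	.	.	UUY
nd5	PCG	L	7790	6260	1529	ATT	TAA	.
trnH	tRNA	L	7872	7806	65	.	.	CAY
nd4	PCG	L	9213	7872	1340	ATG	TAA	.
nd4L	PCG	L	9491	9213	277	ATG	TAA	.
trnT	tRNA	H	9465	9532	68	.	.	ACN
trnP	tRNA	L	9591	9531	59	.	.	CCN
nd6	PCG	H	9611	10040	430	ATT	TAA	.
cytb	PCG	H	10377	11364	988	.	.	.
trnS-ucn	tRNA	H	11367	11432	66	.	.	UCN
nd1	PCG	L	12378	11449	928	TTG	TAG	.
trnL-cun	tRNA	L	12455	12388	66	.	.	CUN
rrnL	rRNA	L	13780	12476	1303	.	.	.
trnV	tRNA	L	13852	13804	47	.	.	GUN
rrnS	rRNA	L	13863	14139	277	.	.	.
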