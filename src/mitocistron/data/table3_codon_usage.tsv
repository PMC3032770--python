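# Maruca vitrata mitochondrial codon usage (14 PCGs, invertebrate
# mitochondrial code: AGR=Ser, AUA=Met, UGA=Trp). `count` and `rscu` are the
# published values. The published UCA count (12.0) is inconsistent with its
# own RSCU (2.06) and with the other Ser-family parentheticals, which all
# imply a count near 75; `corrected_count` carries that reconstruction for
# the single affected row and repeats `count` elsewhere.
codon	aa	count	rscu	corrected_count
UUU	F	315.0	1.82	315.0
UUC	F	31.0	0.18	31.0
UUA	L	426.0	5.26	426.0
UUG	L	9.0	0.11	9.0
CUU	L	26.0	0.32	26.0
CUC	L	2.0	0.02	2.0
CUA	L	23.0	0.28	23.0
CUG	L	0.0	0.00	0.0
AUU	I	394.0	1.91	394.0
AUC	I	18.0	0.09	18.0
AUA	M	240.0	1.85	240.0
AUG	M	19.0	0.15	19.0
GUU	V	71.0	2.07	71.0
GUC	V	4.0	0.12	4.0
GUA	V	59.0	1.72	59.0
GUG	V	3.0	0.09	3.0
UCU	S	98.0	2.69	98.0
UCC	S	8.0	0.22	8.0
UCA	S	12.0	2.06	75.0
UCG	S	1.0	0.05	1.0
CCU	P	74.0	2.47	74.0
CCC	P	8.0	0.27	8.0
CCA	P	38.0	1.27	38.0
CCG	P	0.0	0.00	0.0
ACU	T	83.0	2.35	83.0
ACC	T	8.0	0.23	8.0
ACA	T	49.0	1.39	49.0
ACG	T	1.0	0.03	1.0
GCU	A	75.0	2.52	75.0
GCC	A	9.0	0.30	9.0
GCA	A	35.0	1.18	35.0
GCG	A	0.0	0.00	0.0
UAU	Y	169.0	1.88	169.0
UAC	Y	11.0	0.12	11.0
UAA	*	10.0	1.82	10.0
UAG	*	1.0	0.18	1.0
CAU	H	60.0	1.82	60.0
CAC	H	6.0	0.18	6.0
CAA	Q	54.0	1.96	54.0
CAG	Q	1.0	0.04	1.0
AAU	N	202.0	1.87	202.0
AAC	N	14.0	0.13	14.0
AAA	K	73.0	1.70	73.0
AAG	K	13.0	0.30	13.0
GAU	D	55.0	1.75	55.0
GAC	D	8.0	0.25	8.0
GAA	E	68.0	1.89	68.0
GAG	E	4.0	0.11	4.0
UGU	C	28.0	1.87	28.0
UGC	C	2.0	0.13	2.0
UGA	W	88.0	1.96	88.0
UGG	W	2.0	0.04	2.0
CGU	R	12.0	0.94	12.0
CGC	R	0.0	0.00	0.0
CGA	R	37.0	2.90	37.0
CGG	R	2.0	0.16	2.0
AGU	S	31.0	0.85	31.0
AGC	S	1.0	0.03	1.0
AGA	S	76.0	2.09	76.0
AGG	S	0.0	0.00	0.0
GGU	G	57.0	1.19	57.0
GGC	G	0.0	0.00	0.0
GGA	G	117.0	2.45	117.0
GGG	G	17.0	0.36	17.0
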