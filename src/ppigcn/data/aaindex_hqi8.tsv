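# HQI8: eight high-quality AAindex1 physico-chemical indices (consensus
# fuzzy-clustering cluster centres). Values transcribed from the published
# AAindex1 entries for the eight accessions; one column per index, one row
# per standard residue (three-letter code).
aa	BLAM930101	BIOV880101	MAXF760101	TSAJ990101	NAKH920108	CEDJ970104	LIFS790101	MIYS990104
ALA	0.96	16.0	1.43	89.3	9.36	7.9	0.92	-0.04
ARG	0.77	-70.0	1.18	190.3	0.27	4.9	0.93	0.07
ASN	0.39	-74.0	0.64	122.4	2.31	4.0	0.60	0.13
ASP	0.42	-78.0	0.92	114.4	0.94	5.5	0.48	0.19
CYS	0.42	168.0	0.94	102.5	2.56	1.9	1.16	-0.38
GLN	0.80	-73.0	1.22	146.9	1.14	4.4	0.95	0.14
GLU	0.53	-106.0	1.67	138.8	0.94	7.1	0.61	0.23
GLY	0.00	-13.0	0.46	63.8	6.17	7.1	0.61	0.09
HIS	0.57	50.0	0.98	157.5	0.47	2.1	0.93	-0.04
ILE	0.84	151.0	1.04	163.0	13.73	5.2	1.81	-0.34
LEU	0.92	145.0	1.36	163.1	16.64	8.6	1.30	-0.37
LYS	0.73	-141.0	1.27	165.1	0.58	6.7	0.70	0.33
MET	0.86	124.0	1.53	165.8	3.93	2.4	1.19	-0.30
PHE	0.59	189.0	1.19	190.8	10.99	3.9	1.25	-0.38
PRO	-2.50	-20.0	0.49	121.6	1.96	5.3	0.40	0.19
SER	0.53	-70.0	0.70	94.2	5.58	6.6	0.82	0.12
THR	0.54	-38.0	0.78	119.6	4.68	5.3	1.12	0.03
TRP	0.58	145.0	1.01	226.4	2.20	1.2	1.54	-0.33
TYR	0.72	53.0	0.69	194.6	3.13	3.1	1.53	-0.29
VAL	0.63	123.0	0.98	138.2	12.43	6.8	1.81	-0.29
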