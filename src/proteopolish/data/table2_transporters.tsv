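# Organization and observation of ABC-type carbohydrate uptake transporter
# clusters (transcribed from the published transporter table for
# C. stercorarium DSM8532).  One row per contiguous cluster; subunit orders
# are dash-separated (S solute-binding, M transmembrane, N nucleotide-binding,
# X no match) under the IMG/ER and ABCdb annotations; coverage lists the
# peptide coverage percent of each gene in cluster order, slash-separated.
# family CUT2 marks Carbohydrate Uptake Transporter family 2 (starred rows).
cluster	strand	img_order	abcdb_order	coverage	family
Clst_0059-0061	+	S-S-M	M-M-X	0/4/11	CUT1
Clst_0109-0112	+	M-M-S-S	M-M-X-S	0/0/0/0	CUT1
Clst_0194-0196	+	S-S-M	S-M-M	53/10/13	CUT1
Clst_0200-0202	+	S-S-M	M-M-S	0/0/2	CUT1
Clst_0209-0211	+	S-M-S	S-M-M	4/0/0	CUT1
Clst_0215-0217	+	S-S-M	M-M-S	0/0/37	CUT1
Clst_0218-0221	+	S-S-S-M	S-S-M-M	8/16/0/0	CUT1
Clst_0228-0230	+	M-M-S	M-M-S	0/0/36	CUT1
Clst_0432-0434	+	M-M-S	M-M-S	0/0/10	CUT1
Clst_0444-0446	-	S-M-S	S-M-M	0/0/5	CUT1
Clst_0456-0460	+	N-N-M-S-M	N-N-M-M-S	12/2/0/2/9	CUT2
Clst_0472-0473	+	M-M	M-M	0/0	CUT1
Clst_0476	+	S	S	0	CUT1
Clst_0479-0481	+	S-M-M	S-M-M	34/0/5	CUT1
Clst_0582	-	S	S	0	CUT1
Clst_0627-0629	+	S-M-M	S-M-M	24/3/7	CUT1
Clst_0666-0667	+	S-S	X-M	0/0	CUT1
Clst_0673-0674	+	M-M	M-M	0/0	CUT1
Clst_0797-0799	-	M-M-S	M-M-S	16/3/4	CUT1
Clst_0805-0807	-	M-M-S	M-M-X	18/0/0	CUT1
Clst_0848-0850	-	S-M-M	S-M-M	4/0/34	CUT1
Clst_0934-0936	+	M-S-S	S-M-M	24/0/3	CUT1
Clst_0969-0971	+	S-S-M	M-M-S	0/0/6	CUT1
Clst_0993-0995	+	S-S-S	M-M-S	0/0/4	CUT1
Clst_1007-1008	+	M-S	M-M	0/0	CUT1
Clst_1068-1070	+	M-S-S	S-M-M	5/0/0	CUT1
Clst_1073-1075	+	S-M-S	M-M-S	0/0/18	CUT1
Clst_1077-1079	+	M-M-S	S-M-M	3/4/0	CUT1
Clst_1083-1085	+	S-S-M	M-M-S	0/0/18	CUT1
Clst_1566-1567	-	M-S	M-M	0/0	CUT1
Clst_1587-1589	-	M-S-S	S-M-M	0/0/29	CUT1
Clst_1635-1637	+	S-M-S	S-M-M	24/0/0	CUT1
Clst_2117-2119	-	M-M-S	M-M-S	0/0/0	CUT1
Clst_2139-2141	-	S-M-M	S-M-M	0/0/15	CUT1
Clst_2159-2161	-	M-M-S	S-M-M	14/22/28	CUT1
Clst_2245-2247	-	S-M-M	S-M-M	0/0/36	CUT1
Clst_2458-2460	+	M-N-S	S-N-M	59/69/9	CUT2
Clst_2539-2541	-	S-M-S	S-M-M	28/0/0	CUT1
Clst_2544	-	M	S	23	CUT1
Clst_2579	-	N	N	41	CUT1
Clst_2595-2597	-	S-S-M	S-M-M	0/0/43	CUT1
Clst_2619-2621	-	S-M-S	M-M-X	28/4/9	CUT1
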