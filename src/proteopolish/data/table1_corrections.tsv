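# Base changes, additions and deletions suggested by the RNA-seq transcriptome
# (transcribed from the published corrections table for C. stercorarium DSM8532).
# position: genome position in the corrected sequence, or the former position
#   for deleted bases.  offset: net length change; NA = not applied.
# alt_genome: Y if corroborated by the independently derived genome sequence.
# review_corroborated: Y for rows where the transcriptome corroborates a change
#   suggested by the annotation-improvement review (bold rows in the source).
interval	position	original	corrected	offset	alt_genome	review_corroborated
Clst_0020/21	21928	G	-	-1	Y	N
Clst_0024	25417	A	G	NA	Y	N
Clst_0030/1	31758	T	-	-1	Y	N
Clst_0035/6	37728	-	A	1	Y	N
Clst_0081	88853	A	T	NA	Y	N
Clst_0081	88886	C	A	NA	Y	N
Clst_0130	149305	-	A	1	Y	Y
Clst_0131/2	150526	-	A	1	Y	N
Clst_0269	313700	A	G	0	Y	N
Clst_0746	820762	-	A	1	Y	Y
Clst_0755/6	828349	-	T	1	Y	N
Clst_0791/2	868841	C	A	0	Y	N
Clst_0847	937715	-	C	1	Y	N
Clst_0897/8	995753	-	A	1	Y	N
Clst_0899/900	998883	C	A	NA	Y	N
Clst_0972/3	1090847	-	A	1	Y	N
Clst_0992	1116366	-	A	1	Y	Y
Clst_1060	1201128	-	A	1	Y	Y
Clst_1117	1271246	AT	-	-2	Y	Y
Clst_1187	1342072	T	A	NA	Y	N
Clst_1286/7	1442396	-	T	1	Y	N
CLst_1298/9	1457047	-	T	1	Y	N
Clst_1339/40	1499569	A	-	-1	Y	N
Clst_1341	1502214	A	T	0	Y	N
Clst_1420/1	1596278	A	T	0	Y	N
Clst_1435	1606866	-	A	1	Y	N
Clst_1435	1606893	T	-	-1	Y	N
Clst_1474/5	1649400	-	T	1	Y	N
Clst_1511/2	1694436	A	T	0	N	N
Clst_1524/5	1707519	T	-	-1	N	N
Clst_1542/3	1724606	C	T	0	N	N
Clst_1543	1725709	T	C	0	Y	N
Clst_1605/6	1809359	-	T	1	Y	N
Clst_1771/3	2005558	A	T	0	N	N
Clst_1893	2151838	AA	GG	0	Y	N
Clst_2041/2	2322549	T	A	0	N	N
Clst_2046	2314413	-	C	1	N	N
Clst_2051	2322540	-	C	1	N	N
Clst_2090/1	2365983	G	T	0	N	N
Clst_2360	2656461	-	CTC	NA	N	N
Clst_2564/5	2854567	-	T	1	Y	N
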