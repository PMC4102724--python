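# Curated pathway role catalog: gene symbol -> product-name patterns
# (case-insensitive substrings) used to match annotation product strings.
# Pathways follow the central-metabolism layout of thermophilic clostridia:
# glycolysis (cellobiose/glucose to PEP), the oxidative and non-oxidative
# pentose phosphate pathway, and PEP/pyruvate conversion.
pathway	role	patterns
glycolysis	cep	cellobiose phosphorylase
glycolysis	pmu	phosphoglucomutase
glycolysis	glk	glucokinase
glycolysis	gpi	glucose-6-phosphate isomerase
glycolysis	pfk	phosphofructokinase;6-phosphofructokinase
glycolysis	fba	fructose-bisphosphate aldolase;fructose bisphosphate aldolase
glycolysis	tpi	triosephosphate isomerase;triose-phosphate isomerase
glycolysis	gap	glyceraldehyde-3-phosphate dehydrogenase
glycolysis	pgk	phosphoglycerate kinase
glycolysis	pgm	phosphoglycerate mutase
glycolysis	eno	enolase
pentose_phosphate	ari	arabinose isomerase
pentose_phosphate	rik	ribulose kinase;ribulokinase
pentose_phosphate	xyi	xylose isomerase
pentose_phosphate	xyk	xylulose kinase;xylulokinase
pentose_phosphate	rep	ribulose-5-phosphate 4-epimerase;ribulose-phosphate 4-epimerase
pentose_phosphate	rpe	ribulose-5-phosphate 3-epimerase;ribulose-phosphate 3-epimerase
pentose_phosphate	gpd	glucose-6-phosphate 1-dehydrogenase;glucose-6-phosphate dehydrogenase
pentose_phosphate	pgl	6-phosphogluconolactonase;phosphoglucolactonase
pentose_phosphate	pdg	6-phosphogluconate dehydrogenase;phosphogluconate dehydrogenase
pentose_phosphate	rpi	ribose-5-phosphate isomerase
pentose_phosphate	trk	transketolase
pentose_phosphate	tal	transaldolase
pep_pyruvate	pyk	pyruvate kinase
pep_pyruvate	ppd	pyruvate phosphate dikinase;pyruvate, phosphate dikinase
pep_pyruvate	ldh	lactate dehydrogenase
pep_pyruvate	pdh	pyruvate dehydrogenase
pep_pyruvate	por	pyruvate:ferredoxin oxidoreductase;pyruvate ferredoxin oxidoreductase
pep_pyruvate	pat	phosphate acetyltransferase;phosphotransacetylase
pep_pyruvate	ack	acetate kinase
pep_pyruvate	ald	aldehyde dehydrogenase
pep_pyruvate	adh	alcohol dehydrogenase
pep_pyruvate	pep	phosphoenolpyruvate carboxykinase
pep_pyruvate	mdh	malate dehydrogenase
pep_pyruvate	mle	malic enzyme
pep_pyruvate	oad	oxaloacetate decarboxylase
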