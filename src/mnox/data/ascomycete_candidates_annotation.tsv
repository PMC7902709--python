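query_id	jgi_id	jgi_annotation	subject_accession	description	genome	raw_score	e_value	percent_identity	cazy_family	cofactor_class
OAL06359.1	211028|Stasp1	Tyrosinase	KAF2023949.1	Di-copper-center-containing protein	Setomelanomma holmii	550	0.0	68	AA1_3	Cu
OAL02734.1	119700|Stasp1	Multicopper oxidase	KAF2031423.1	Cupredoxin	Setomelanomma holmii	518	8e-179	81	AA1_3	Cu
OAL06112.1	323207|Stasp1	Glyoxal oxidase, chitinase, CBM 18	KAF1842338.1	Carbohydrate binding module family 18	Cucurbitaria berberidis CBS 394.84	1146	0.0	83	AA5_1, CBM 18	Cu
OAK94057.1	330396|Stasp1	Superoxide dismutase (Cu/Zn)	XP_033452169.1	Copper/zinc binding superoxide dismutase	Didymella exigua CBS 183.55	294	3e-100	95		Cu/Zn
OAK99381.1	251441|Stasp1	FAD-binding protein	KAF2849814.1	FAD binding domain-containing protein	Plenodomus tracheiphilus IPT5	883	0.0	75		FAD
OAL03573.1	291332|Stasp1	FAD-binding protein	KAF2035237.1	FAD binding domain-containing protein	Setomelanomma holmii	1070	0.0	83		FAD
OAK93932.1	261684|Stasp1	GMC oxidoreductase	OWY46284.1	Alcohol oxidase	Alternaria alternata	1189	0.0	83	AA3_3	FAD
OAK94822.1	260169|Stasp1	Copper amine oxidase	KAF1915680.1	Copper amine oxidase	Ampelomyces quisqualis	65.5	1e-10	77		Cu
OAL06123.1	343359|Stasp1	Succinate-semialdehyde dehydrogenase [NAD(P)+]	KAF3004401.1	Succinate-semialdehyde dehydrogenase NADP+ linked	Curvularia kusanoi	977	0.0	90		NAD(P)
OAK96127.1	296929|Stasp1	Superoxide dismutase (Fe/Mn)	KAF2036800.1	Superoxide dismutase (Fe/Mn)	Setomelanomma holmii	450	1e-158	93		Fe/Mn
OAL54547.1	640056|Pyrsp1	FAD-binding protein	KAF1846528.1	FAD-binding domain-containing protein	Cucurbitaria berberidis CBS 394.84	661	0.0	69		FAD
OAL53386.1	678105|Pyrsp1	GMC oxidoreductase	KAF1845720.1	GMC oxidoreductase	Cucurbitaria berberidis CBS 394.84	1131	0.0	79	AA3	FAD
OAL43510.1	524095|Pyrsp1	FAD-binding protein	KAF1843187.1	Bifunctional solanapyrone synthase	Cucurbitaria berberidis CBS 394.84	775	0.0	75	AA7	FAD
OAL51393.1	586913|Pyrsp1	Copper amine oxidase	KAF1851230.1	Copper amine oxidase-like protein	Cucurbitaria berberidis CBS 394.84	1316	0.0	92		Cu
OAL49332.1	681286|Pyrsp1	FAD-binding protein, berberine-like	KAF1846047.1	FAD-binding domain-containing protein	Cucurbitaria berberidis CBS 394.84	1019	0.0	76		FAD
XP_018032780.1	1152844|Parsp1	GMC oxidoreductase	KAF2439767.1	GMC oxidoreductase	Karstenula rhodostoma CBS 690.94	1232	0.0	93	AA3	FAD
XP_018030874.1	1129270|Parsp1	Multicopper oxidase	KAF1971487.1	Cupredoxin	Bimuria novae-zelandiae CBS 107.79	201	6e-59	86	AA1_3	Cu
XP_018033536.1	961577|Parsp1	Peroxidase, heme-binding	KAF1965650.1	Heme peroxidase	Bimuria novae-zelandiae CBS 107.79	883	0.0	71	AA2	Fe/heme
XP_018035449.1	827017|Parsp1	2-methylcitrate dehydratase	KAF1966230.1	2-methylcitrate dehydratase	Bimuria novae-zelandiae CBS 107.79	1077	0.0	93		Fe-S
XP_018035114.1	1165126|Parsp1	GMC oxidoreductase	KAF2448902.1	GMC oxidoreductase	Karstenula rhodostoma CBS 690.94	1046	0.0	87	AA3_2	FAD
XP_018035504.1	1165466|Parsp1	Alkyl hydroperoxide reductase, peroxiredoxin	KAF2446886.1	AhpC/TSA family protein-like protein (thioredoxin-like peroxidase)	Karstenula rhodostoma CBS 690.94	335	7e-116	97		peroxidatic-Cys
XP_018033970.1	1188260|Parsp1	FAD-binding protein	KAF2445831.1	FAD-binding domain-containing protein	Karstenula rhodostoma CBS 690.94	1009	0.0	94		FAD
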