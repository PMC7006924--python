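gene_id	accession	description	pbtx_fc	pbtx_p	kbrevis_fc	kbrevis_p	symbiont
Cluster599840	NA	NA	0.18	0.0322	1.64	0.2997	0
Cluster45626	gi|1176095254	actin-related protein 2	1.56	0.0219	0.40	0.0131	0
Cluster30	gi|156221418	predicted protein	1.57	0.0308	11.32	0.0041	0
Cluster78396	gi|1176105383	uncharacterized skeletal organic matrix protein 5-like	11.00	0.0494	9.72	0.0467	0
Cluster153015	gi|1191069530	uncharacterized protein LOC110251054	5.23	0.0000	3.31	0.0000	0
Cluster97665	gi|1176107158	failed axon connections homolog	4.64	0.0112	3.02	0.0378	0
Cluster78285	gi|1176094913	neurogenic locus Notch protein-like	1.63	0.0074	2.53	0.0000	0
Cluster74461	gi|1005492381	histone H2A-like	1.71	0.0242	1.56	0.5163	0
Cluster72128	gi|1129189947	photosystem I subunit II (chloroplast)	2.12	0.0161	1.34	0.2022	1
Cluster120960	gi|156384837	histone H4-like	2.02	0.0000	1.30	0.4262	0
Cluster54901	gi|134104063	chloroplast soluble peridinin-chlorophyll a-binding protein precursor	1.74	0.0000	1.29	0.0016	0
Cluster92319	gi|156308410	histone H2B	3.02	0.0128	1.12	0.1788	0
Cluster42011	gi|1176106978	trichohyalin-like isoform X2	1.72	0.0282	1.08	0.9878	0
Cluster201619	gi|1005436313	Calreticulin	1.61	0.0215	0.80	0.0633	0
Cluster480843	NA	NA	1.85	0.0274	0.59	0.0190	0
Cluster12861	gi|1176065290	vacuolar protein sorting-associated protein 35	1.05	0.0226	0.49	0.0000	0
Cluster86218	gi|1005455133	centromere-associated protein E-like	1.06	0.2853	0.48	0.0207	0
Cluster77817	gi|1176083360	thiosulfate sulfurtransferase-like	1.30	0.2002	0.47	0.0483	0
Cluster70872	gi|1176102334	6-phosphogluconate dehydrogenase, decarboxylating-like	1.31	0.1303	0.45	0.0492	0
Cluster44622	gi|1176099874	protein kinase C and casein kinase substrate in neurons protein 1 isoform X3	1.22	0.2016	0.44	0.0437	0
Cluster36510	gi|1176074793	3-phosphoinositide-dependent protein kinase 1	1.29	0.2687	0.43	0.0460	0
Cluster14994	gi|1176081911	spermatogenesis-associated protein 20	0.96	0.3760	0.42	0.0433	0
Cluster38861	gi|514686106	hypothetical protein PTSG_08380	1.38	0.2078	0.41	0.0404	0
Cluster39017	gi|1263131715	Trifunctional enzyme subunit beta, mitochondrial	0.93	0.1247	0.40	0.0029	0
Cluster90375	gi|1005435074	proteasomal ubiquitin receptor ADRM1-like	0.72	0.1822	0.40	0.0396	0
Cluster72289	gi|1005478902	prohibitin-2 isoform X1	1.37	0.1582	0.38	0.0403	0
Cluster13855	gi|1176083171	centrosomal protein of 290 kDa-like	0.79	0.0213	0.36	0.0082	0
Cluster21163	gi|452944860	photosystem I P700 apoprotein A2 (chloroplast)	1.22	0.1645	0.33	0.0359	1
Cluster77998	gi|1176061994	Krueppel-like factor 16	1.14	0.2920	0.32	0.0214	0
Cluster135790	gi|1005469133	Seed maturation protein domain protein	0.87	0.0882	5.46	0.0194	0
Cluster563359	gi|999976565	succinate--CoA ligase (ADP/GDP-forming) subunit alpha, mitochondrial-like	0.92	0.5393	2.99	0.0236	0
Cluster12612	gi|156224519	Endoplasmin	1.25	0.2646	2.73	0.0000	0
Cluster6698	gi|999985476	NAD(P) transhydrogenase, mitochondrial	1.13	0.7138	2.69	0.0019	0
Cluster8701	gi|1176081387	cleavage stimulation factor subunit 2-like	1.06	0.3771	2.65	0.0355	0
Cluster110390	gi|931444489	metal-dependent hydrolase	1.41	0.0079	2.56	0.0058	0
Cluster665	NA	NA	1.05	0.3370	2.55	0.0155	0
Cluster57194	gi|1129196481	2-hydroxyacid dehydrogenase	0.71	0.2976	2.49	0.0479	1
Cluster3401	gi|828223890	THO complex subunit 2	0.87	0.3766	2.46	0.0322	0
Cluster71042	gi|156376666	heterogeneous nuclear ribonucleoprotein A/B isoform X1	0.98	0.4789	2.46	0.0406	0
Cluster137452	gi|1005485438	myosin-2 essential light chain-like	1.19	0.1023	2.43	0.0008	0
Cluster68537	gi|1176073868	cartilage matrix protein-like	1.21	0.1569	2.43	0.0000	0
Cluster1877	gi|1176099008	Intersectin-1	1.37	0.1259	2.33	0.0111	0
Cluster60925	gi|1263126539	Cathepsin B	1.32	0.3480	2.28	0.0013	0
Cluster89694	gi|1270045038	Proteasome subunit alpha type-5	1.11	0.8611	2.18	0.0125	0
Cluster63543	gi|1176121623	cathepsin L1-like	1.00	0.7961	2.18	0.0346	0
Cluster80745	gi|1176123940	cytochrome b-c1 complex subunit Rieske, mitochondrial-like	1.17	0.8346	1.94	0.0001	0
Cluster24085	gi|944358134	Tubulin alpha-1C chain	0.83	0.8934	1.91	0.0291	0
Cluster29482	gi|1270036269	glucosidase 2 subunit beta-like	0.91	0.3125	1.91	0.0448	0
Cluster10800	gi|156219690	coatomer subunit gamma-2	0.66	0.0663	1.90	0.0005	0
Cluster98716	gi|1176090182	ras-related protein Rab-11A	1.01	0.6742	1.90	0.0098	0
Cluster40025	gi|1263121217	Protein disulfide-isomerase A6	1.07	0.5999	1.82	0.0031	0
Cluster101211	gi|1176117806	glutathione S-transferase-like	0.83	0.6735	1.73	0.0023	0
Cluster136968	gi|1176092520	neuronal pentraxin-2-like	1.26	0.1302	1.72	0.0289	0
Cluster111088	gi|1005447951	NADH dehydrogenase (ubiquinone) 1 beta subcomplex subunit 8, mitochondrial	1.61	0.1944	1.71	0.0095	0
Cluster58031	gi|1263138886	protein disulfide-isomerase tigA precursor	0.97	0.8207	1.70	0.0065	0
Cluster41678	gi|1005486638	phosphatidylserine decarboxylase	1.00	0.7788	1.68	0.0018	0
Cluster5009	gi|1176107568	dyp-type peroxidase family protein	1.03	0.0076	1.64	0.0010	0
Cluster15920	gi|1176120735	predicted protein	1.08	1.0000	1.57	0.0133	0
Cluster32856	gi|1176110238	protein disulfide isomerase	1.22	0.2482	1.56	0.0060	0
Cluster225948	gi|1101333444	fructose-bisphosphate aldolase	0.87	0.0222	1.52	0.0000	0
Cluster20910	gi|749717734	Transposon Tf2-6 polyprotein	0.94	0.0713	1.52	0.0002	0
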