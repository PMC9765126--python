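family	activity
# Curated default mapping of CAZy families/subfamilies to their main
# characterized target activity.  Subfamily entries override family entries.
GH5	cellulases
GH6	cellulases
GH7	cellulases
GH8	cellulases
GH9	cellulases
GH12	cellulases
GH44	cellulases
GH45	cellulases
GH48	cellulases
GH124	cellulases
GH10	xylanases/xyloglucanases
GH11	xylanases/xyloglucanases
GH30	xylanases/xyloglucanases
GH74	xylanases/xyloglucanases
GH98	xylanases/xyloglucanases
GH1	beta-glucosidases/beta-xylosidases
GH3	beta-glucosidases/beta-xylosidases
GH39	beta-glucosidases/beta-xylosidases
GH52	beta-glucosidases/beta-xylosidases
GH116	beta-glucosidases/beta-xylosidases
GH120	beta-glucosidases/beta-xylosidases
GH18	chitinases/chitosanases
GH19	chitinases/chitosanases
GH46	chitinases/chitosanases
GH75	chitinases/chitosanases
GH80	chitinases/chitosanases
GH13	alpha-glucanases
GH15	alpha-glucanases
GH31	alpha-glucanases
GH57	alpha-glucanases
GH77	alpha-glucanases
GH97	alpha-glucanases
GH119	alpha-glucanases
GH126	alpha-glucanases
GH133	alpha-glucanases
GH16	beta-glucanases
GH17	beta-glucanases
GH55	beta-glucanases
GH64	beta-glucanases
GH81	beta-glucanases
GH128	beta-glucanases
GH26	mannanases
GH76	mannanases
GH113	mannanases
GH134	mannanases
GH5_7	mannanases
GH53	arabinogalactanases
GH165	arabinogalactanases
GH43	other hemicellulases
GH51	other hemicellulases
GH54	other hemicellulases
GH62	other hemicellulases
GH67	other hemicellulases
GH115	other hemicellulases
CE1	other hemicellulases
CE2	other hemicellulases
CE3	other hemicellulases
CE5	other hemicellulases
CE6	other hemicellulases
CE7	other hemicellulases
GH28	pectinases
GH78	pectinases
GH88	pectinases
GH105	pectinases
PL1	pectinases
PL2	pectinases
PL3	pectinases
PL9	pectinases
PL10	pectinases
PL11	pectinases
PL22	pectinases
PL26	pectinases
CE8	pectinases
CE12	pectinases
GH50	carragenases/agarases
GH82	carragenases/agarases
GH86	carragenases/agarases
GH118	carragenases/agarases
GH150	carragenases/agarases
GH167	carragenases/agarases
GH16_3	carragenases/agarases
GH23	peptidoglycanases
GH24	peptidoglycanases
GH25	peptidoglycanases
GH73	peptidoglycanases
GH102	peptidoglycanases
GH103	peptidoglycanases
GH104	peptidoglycanases
GH108	peptidoglycanases
CE4	peptidoglycanases
GH20	glycoconjugate-degrading enzymes
GH29	glycoconjugate-degrading enzymes
GH33	glycoconjugate-degrading enzymes
GH35	glycoconjugate-degrading enzymes
GH36	glycoconjugate-degrading enzymes
GH38	glycoconjugate-degrading enzymes
GH84	glycoconjugate-degrading enzymes
GH85	glycoconjugate-degrading enzymes
GH89	glycoconjugate-degrading enzymes
GH92	glycoconjugate-degrading enzymes
GH95	glycoconjugate-degrading enzymes
GH101	glycoconjugate-degrading enzymes
GH109	glycoconjugate-degrading enzymes
GH110	glycoconjugate-degrading enzymes
GH123	glycoconjugate-degrading enzymes
GH129	glycoconjugate-degrading enzymes
AA9	lytic polysaccharide monooxygenases
AA10	lytic polysaccharide monooxygenases
AA11	lytic polysaccharide monooxygenases
AA13	lytic polysaccharide monooxygenases
AA14	lytic polysaccharide monooxygenases
AA15	lytic polysaccharide monooxygenases
AA16	lytic polysaccharide monooxygenases
AA17	lytic polysaccharide monooxygenases
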