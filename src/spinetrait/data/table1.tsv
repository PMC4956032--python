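taxon	femur_cm	projections	femur_estimated
Achillobator	50.5	0	0
Acrocanthosaurus	127.7	1	0
Albertosaurus	106.6	1	0
Allosaurus	100.1	1	0
Archaeopteryx	5.8	0	0
Archaeornithomimus	31.4	0	0
Avimimus	18.6	0	0
Bambiraptor	17	0	0
Baryonyx	120	1	1
Buitreraptor	14.5	0	1
Carnotaurus	103	1	0
Caudipteryx	15.2	0	0
Ceratosaurus	62	0	0
Chirostenotes	31	0	0
Citipati	41.1	0	0
Coelophysis	21.74	0	0
Coelurus	21	0	0
Compsognathus	11	0	0
Daspletosaurus	100	1	0
Deinonychus	33.6	0	0
Dilophosaurus	58.7	0	0
Eoraptor	15.2	0	0
Falcarius	34	0	0
Fukuiraptor	50.7	0	0
Garudimimus	49.9	1	0
Guanlong	41.6	0	0
Herrerasaurus	35.4	0	0
Huaxiagnathus	16.3	0	0
Jinfengopteryx	7.032	0	0
Khaan	18.8	0	0
Liliensternus	44.9	0	0
Majungasaurus	56.80	1	0
Masiakasaurus	19.36	0	0
Mei	8.1	0	0
Microraptor	7.59	0	0
Microvenator	12.4	0	0
Mirischia	16.5	0	0
Mononykus	13.84	0	0
Neovenator	75	1	0
Ornitholestes	21.00	0	0
Ornithomimus	50	0	0
Rahonavis	8.8	0	0
Saurornithoides	14	0	0
Saurornitholestes	22.5	0	0
Shenzhousaurus	19.1	0	0
Shuvuuia	12.45	0	0
Sinosauropteryx	8.64	0	0
Sinovenator	11.11	0	0
Spinosaurus	61	0	0
Staurikosaurus	23.5	0	0
Struthiomimus	51.3	0	0
Torvosaurus	83	1	0
Troodon	30	0	0
Tyrannosaurus	134.25	1	0
Tyrannotitan	140	1	0
Velociraptor	18.7	0	0
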