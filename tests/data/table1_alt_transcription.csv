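species,projections,femur_length_cm
Velociraptor,0,18.7
Tyrannotitan,1,140
Tyrannosaurus,1,134.25
Troodon,0,30
Torvosaurus,1,83
Struthiomimus,0,51.3
Staurikosaurus,0,23.5
Spinosaurus,0,61
Sinovenator,0,11.11
Sinosauropteryx,0,8.64
Shuvuuia,0,12.45
Shenzhousaurus,0,19.1
Saurornitholestes,0,22.5
Saurornithoides,0,14
Rahonavis,0,8.8
Ornithomimus,0,50
Ornitholestes,0,21.00
Neovenator,1,75
Mononykus,0,13.84
Mirischia,0,16.5
Microvenator,0,12.4
Microraptor,0,7.59
Mei,0,8.1
Masiakasaurus,0,19.36
Majungasaurus,1,56.80
Liliensternus,0,44.9
Khaan,0,18.8
Jinfengopteryx,0,7.032
Huaxiagnathus,0,16.3
Herrerasaurus,0,35.4
Guanlong,0,41.6
Garudimimus,1,49.9
Fukuiraptor,0,50.7
Falcarius,0,34
Eoraptor,0,15.2
Dilophosaurus,0,58.7
Deinonychus,0,33.6
Daspletosaurus,1,100
Compsognathus,0,11
Coelurus,0,21
Coelophysis,0,21.74
Citipati,0,41.1
Chirostenotes,0,31
Ceratosaurus,0,62
Caudipteryx,0,15.2
Carnotaurus,1,103
Buitreraptor,0,14.5
Baryonyx,1,120
Bambiraptor,0,17
Avimimus,0,18.6
Archaeornithomimus,0,31.4
Archaeopteryx,0,5.8
Allosaurus,1,100.1
Albertosaurus,1,106.6
Acrocanthosaurus,1,127.7
Achillobator,0,50.5
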