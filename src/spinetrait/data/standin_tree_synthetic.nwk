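(Eoraptor:1,(Herrerasaurus:0.0181818181818,Staurikosaurus:0.0181818181818):0.981818181818,((Coelophysis:0.0181818181818,Liliensternus:0.0181818181818):0.927272727273,(Dilophosaurus:0.909090909091,((Ceratosaurus:0.0545454545455,(Carnotaurus:0.0363636363636,Majungasaurus:0.0363636363636,Masiakasaurus:0.0363636363636):0.0181818181818):0.836363636364,((Torvosaurus:0.0363636363636,(Baryonyx:0.0181818181818,Spinosaurus:0.0181818181818):0.0181818181818):0.781818181818,((Allosaurus:0.0727272727273,Fukuiraptor:0.0727272727273,(Acrocanthosaurus:0.0363636363636,Neovenator:0.0363636363636,Tyrannotitan:0.0363636363636):0.0363636363636):0.690909090909,((Compsognathus:0.0545454545455,Huaxiagnathus:0.0545454545455,Sinosauropteryx:0.0545454545455,Mirischia:0.0545454545455):0.618181818182,(Coelurus:0.6,Ornitholestes:0.6,((Guanlong:0.0545454545455,(Albertosaurus:0.0363636363636,(Daspletosaurus:0.0181818181818,Tyrannosaurus:0.0181818181818):0.0181818181818):0.0181818181818):0.509090909091,((Shenzhousaurus:0.0727272727273,(Archaeornithomimus:0.0545454545455,Garudimimus:0.0545454545455,(Ornithomimus:0.0181818181818,Struthiomimus:0.0181818181818):0.0363636363636):0.0181818181818):0.418181818182,((Mononykus:0.0181818181818,Shuvuuia:0.0181818181818):0.381818181818,(Falcarius:0.363636363636,((Avimimus:0.0909090909091,Caudipteryx:0.0909090909091,Microvenator:0.0909090909091,(Chirostenotes:0.0363636363636,(Citipati:0.0181818181818,Khaan:0.0181818181818):0.0181818181818):0.0545454545455):0.254545454545,(Archaeopteryx:0.236363636364,(Buitreraptor:0.127272727273,Rahonavis:0.127272727273,(Microraptor:0.0909090909091,(Bambiraptor:0.0727272727273,(Deinonychus:0.0545454545455,(Achillobator:0.0363636363636,(Velociraptor:0.0181818181818,Saurornitholestes:0.0181818181818):0.0181818181818):0.0181818181818):0.0181818181818):0.0181818181818):0.0363636363636):0.109090909091,(Sinovenator:0.0727272727273,Mei:0.0727272727273,Jinfengopteryx:0.0727272727273,(Troodon:0.0181818181818,Saurornithoides:0.0181818181818):0.0545454545455):0.163636363636):0.109090909091):0.0181818181818):0.0363636363636):0.0909090909091):0.0727272727273):0.0363636363636):0.0727272727273):0.0909090909091):0.0545454545455):0.0727272727273):0.0181818181818):0.0363636363636):0.0545454545455);
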