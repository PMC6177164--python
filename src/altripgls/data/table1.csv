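species,family,common_name,cylinder_pct,fw_days,lifespan_days,taxon_class
Amazona amazonica,Psittacidae,Orange-winged amazon,50.8,56,10950,bird
Aphelocoma califórnica,Corvidae,Western scrub jay,76.7,20,5767,bird
Callithrix jacchus,Callitrichidae,Marmoset,31.9,60,8322,mammal
Canis familiaris,Canidae,Domestic dog,79.1,37,8760,mammal
Canis latrans,Canidae,Coyote,95,42,7957,mammal
Canis lupus,Canidae,Wolf,77.3,35,7519,mammal
Cebus apella,Cebidae,Tufted Capuchin monkey,95.9,307,16790,mammal
Columbia livia,Columbidae,White carnea pigeon,32.5,33,12775,bird
Daubentonia madagascariensis,Daubentonidae,Aye aye,51,197,8504.5,mammal
Eulemur fulvus,Lemuridae,Brown lemur,43.3,150,12958,mammal
Eulemur macaco,Lemuridae,Black lemur,51,165,13688,mammal
Eulemur mongoz,Lemuridae,Mongoose lemur,59,135,13213,mammal
Eulemur rubriventer,Lemuridae,Red-bellied lemur,63.8,150,7300,mammal
Garrulus glandarius,Corvidae,Eurasian jay,58.3,20,6533.5,bird
Gorilla gorilla,Hominidae,Gorilla,94.4,1278,20075,mammal
Lemur catta,Lemuridae,Ring-tailed lemur,68.1,150,10950,mammal
Leontopithecus chrysomelas,Callitrichidae,Golden-headed lion tamarin,63,129,7774.5,mammal
Macaca mulatta,Cercopithecidae,Rhesus macaque,80,330,14600,mammal
Melospiza melodia,Emberizidae,Song sparrow,26.5,17,4124.5,bird
Meriones unguiculatus,Muridae,Mongolian gerbil,68.9,25,730,mammal
Pan paniscus,Hominidae,Bonobo,95,1094,19893,mammal
Pan troglodytes,Hominidae,Chimpanzee,100,1460,21681,mammal
Papio anubis,Cercopithecidae,Olive baboon,76.3,420,9198,mammal
Papio hamadryas,Cercopithecidae,Hamadryas baboon,67.8,300,13688,mammal
Pongo pygmaeus,Hominidae,Bornean orangutan,99.1,1936,20513,mammal
Propithecus coquereli,Indriidae,Coquerel's sifaka,36.4,165,9855,mammal
Rhinopithecuas roxellana,Cercopithecidae,Golden snub-nosed monkey,35,365,9490,mammal
Saimiri sciureus,Cebidae,Squirrel monkey,33.7,177,11023,mammal
Sciurus niger,Sciuridae,Fox squirrel,66.9,56,4367.6,mammal
Taeniopygia guttata,Estrildidae,Zebra finch,52.2,21,1642.5,bird
Varecia variegata,Lemuridae,Ruffed lemur,69.7,135,6935,mammal
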