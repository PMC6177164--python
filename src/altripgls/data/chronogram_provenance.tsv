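node	age_ma	source
Aves-Mammalia root	312	TimeTree median for the bird-mammal (sauropsid-synapsid) split
Columba vs other birds sampled	90	TimeTree, Columbiformes vs core landbirds
Amazona vs Passeriformes	63	TimeTree, Psittaciformes-Passeriformes split
Corvidae vs Passerida	40	TimeTree / Oliveros et al. oscine timescale
Aphelocoma-Garrulus	19	TimeTree, crown Corvidae
Melospiza-Taeniopygia	29	TimeTree, Passerellidae vs Estrildidae
Melospiza melodia-M. georgiana	3	TimeTree, congeneric sparrows (32-species tree only)
Laurasiatheria-Euarchontoglires	96	TimeTree, human-dog
Rodentia-Primates	88	TimeTree, human-mouse
Sciurus-Meriones	72	TimeTree, squirrel-related vs mouse-related rodents
Canis latrans vs C. lupus/familiaris	2	published wolf-coyote estimates (1-4 Ma range)
Canis lupus-C. familiaris	0.015	15 kya wolf/dog divergence (study methods)
Primates crown	74	TimeTree / 10kTrees, strepsirrhine-haplorhine
Daubentonia vs other lemurs	59	TimeTree, crown Lemuriformes
Indriidae-Lemuridae	39	TimeTree / 10kTrees
Varecia vs Lemur+Eulemur	29	10kTrees, crown Lemuridae
Lemur-Eulemur	21	10kTrees
Eulemur crown	10	10kTrees; subclades (macaco,fulvus)=5, (mongoz,rubriventer)=8
Platyrrhini-Catarrhini	43	TimeTree / 10kTrees
Cebidae-Callitrichidae	20	10kTrees, crown Platyrrhini (sampled taxa)
Cebus-Saimiri	16	10kTrees
Callithrix-Leontopithecus	11	10kTrees
Cercopithecoidea-Hominoidea	29	TimeTree / 10kTrees, crown Catarrhini
Colobinae-Cercopithecinae	17.5	10kTrees, Rhinopithecus vs Macaca+Papio
Macaca-Papio	12.5	10kTrees
Papio anubis-P. hamadryas	1.8	10kTrees
Pongo vs African apes	15.7	10kTrees / TimeTree
Gorilla vs Pan	8.8	10kTrees / TimeTree
Pan paniscus-P. troglodytes	2.1	10kTrees / TimeTree
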