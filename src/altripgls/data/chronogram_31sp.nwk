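((Columba_livia:90,(Amazona_amazonica:63,((Aphelocoma_californica:19,Garrulus_glandarius:19):21,(Melospiza_melodia:29,Taeniopygia_guttata:29):11):23):27):222,((Canis_latrans:2,(Canis_lupus:0.015,Canis_familiaris:0.015):1.985):94,((Sciurus_niger:72,Meriones_unguiculatus:72):16,((Daubentonia_madagascariensis:59,(Propithecus_coquereli:39,(Varecia_variegata:29,(Lemur_catta:21,((Eulemur_macaco:5,Eulemur_fulvus:5):5,(Eulemur_mongoz:8,Eulemur_rubriventer:8):2):11):8):10):20):15,(((Cebus_apella:16,Saimiri_sciureus:16):4,(Callithrix_jacchus:11,Leontopithecus_chrysomelas:11):9):23,((Rhinopithecus_roxellana:17.5,(Macaca_mulatta:12.5,(Papio_anubis:1.8,Papio_hamadryas:1.8):10.7):5):11.5,(Pongo_pygmaeus:15.7,(Gorilla_gorilla:8.8,(Pan_paniscus:2.1,Pan_troglodytes:2.1):6.7):6.9):13.3):14):31):14):8):216);
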