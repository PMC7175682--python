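bee_species,n_loads,n_localities,pure_load_pct,presence_pct,printed_category,preferred_host,preferred_host_level,genus_top_share_pct,genus_pure_pct
Andrena alfkenella,6,3,33.3,100.0,broadly_oligolectic,Apiaceae,family,,
Andrena bicolor,16,7,37.5,37.5,polylectic_ss,Asteraceae,family,,
Andrena chrysosceles,32,9,43.8,78.1,polylectic_ss,Apiaceae,family,,
Andrena cineraria,9,3,33.3,77.8,polylectic_ss,Brassicaceae,family,,
Andrena dorsata,22,9,50.0,68.2,polylectic_ss,Rosaceae,family,,
Andrena flavipes,45,10,15.6,86.7,polylectic_ss,Asteraceae,family,,
Andrena florea,3,2,100.0,100.0,narrowly_oligolectic,Bryonia dioica,species,100.0,100.0
Andrena haemorrhoa,40,12,10.0,45.0,polylectic_ss,Rosaceae,family,,
Andrena labiata,3,1,0.0,66.7,polylectic_ss,Caryophyllaceae,family,,
Andrena minutula,15,8,20.0,60.0,polylectic_ss,Apiaceae,family,,
Andrena minutuloides,8,2,100.0,100.0,broadly_oligolectic,Apiaceae,family,,
Andrena nigroaenea,16,6,18.8,62.5,polylectic_ss,Apiaceae,family,,
Andrena nitida,23,10,21.7,69.6,polylectic_ss,Brassicaceae,family,,
Andrena scotica,18,7,55.6,77.8,polylectic_ss,Brassicaceae,family,,
Andrena semilaevis,97,9,75.3,97.9,polylectic_strong_preference,Apiaceae,family,,
Andrena subopaca,12,4,33.3,50.0,polylectic_ss,Apiaceae,family,,
Halictus tumulorum,21,10,38.1,71.4,polylectic_ss,Asteraceae,family,,
Lasioglossum albipes,3,2,33.3,66.7,polylectic_ss,Ranunculaceae,family,,
Lasioglossum calceatum,38,11,42.1,68.4,polylectic_ss,Asteraceae,family,,
Lasioglossum fulvicorne,7,2,57.1,71.4,polylectic_ss,Brassicaceae,family,,
Lasioglossum lativentre,9,3,77.8,88.9,polylectic_strong_preference,Fabaceae,family,,
Lasioglossum leucopus,7,6,0.0,57.1,polylectic_ss,Brassicaceae,family,,
Lasioglossum leucozonium,21,6,71.4,100.0,polylectic_strong_preference,Asteraceae,family,,
Lasioglossum malachurum,437,12,53.3,83.3,polylectic_strong_preference,Asteraceae,family,,
Lasioglossum morio,7,5,28.6,42.9,polylectic_ss,Brassicaceae,family,,
Lasioglossum parvulum,7,5,0.0,42.9,polylectic_ss,Rosaceae,family,,
Lasioglossum pauxillum,70,10,45.7,68.6,polylectic_ss,Asteraceae,family,,
Lasioglossum villosulum,25,5,100.0,100.0,broadly_oligolectic,Asteraceae,family,49.3,
Lasioglossum xanthopus,7,3,42.9,85.7,mesolectic,Asteraceae,family,,
Lasioglossum zonulum,4,1,0.0,100.0,polylectic_ss,Rosaceae,family,,
Melitta tricincta,3,1,100.0,100.0,narrowly_oligolectic,Odontites vernus,species,100.0,100.0
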