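bee_species,n_observations,n_loads,obs_plant_species,pollen_plant_species,rarefied_12,obs_plant_families,pollen_plant_families
Andrena alfkenella,10,6,2,7,,1,5
Andrena bicolor,17,16,5,11,9.61,4,9
Andrena chrysosceles,38,32,7,16,13.40,4,8
Andrena cineraria,16,9,6,9,,3,6
Andrena dorsata,34,22,9,15,10.30,5,5
Andrena flavipes,70,45,14,28,18.06,4,12
Andrena haemorrhoa,43,40,6,18,11.03,5,11
Andrena labiata,2,3,1,6,,1,6
Andrena minutula,30,15,9,11,9.78,3,5
Andrena minutuloides,10,8,2,2,,1,1
Andrena nigroaenea,13,16,5,16,11.07,4,10
Andrena nitida,24,23,7,16,14.14,5,12
Andrena scotica,13,18,4,12,11.24,3,9
Andrena semilaevis,127,97,7,18,10.33,3,9
Andrena subopaca,7,12,3,13,11.00,3,8
Halictus tumulorum,23,21,14,19,16.14,5,11
Lasioglossum albipes,3,3,2,4,,2,4
Lasioglossum calceatum,70,38,17,31,19.76,7,16
Lasioglossum fulvicorne,6,7,3,4,,3,4
Lasioglossum lativentre,8,9,3,5,,2,3
Lasioglossum leucopus,5,7,2,8,,2,5
Lasioglossum leucozonium,51,21,9,8,7.56,2,2
Lasioglossum malachurum,553,437,22,50,22.98,8,22
Lasioglossum morio,6,7,6,11,,5,7
Lasioglossum parvulum,6,7,4,9,,4,7
Lasioglossum pauxillum,93,70,17,28,18.09,4,12
Lasioglossum villosulum,32,25,7,5,3.93,1,1
Lasioglossum xanthopus,8,7,1,5,,1,4
Lasioglossum zonulum,7,4,5,9,,4,6
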