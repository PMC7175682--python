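bee_species,family,share_pct
Andrena alfkenella,Apiaceae,97.0
Andrena alfkenella,other,3.0
Andrena bicolor,Asteraceae,29.6
Andrena bicolor,Brassicaceae,21.4
Andrena bicolor,Cucurbitaceae,13.7
Andrena bicolor,Apiaceae,13.7
Andrena bicolor,Campanulaceae,10.5
Andrena bicolor,Liliaceae,7.8
Andrena bicolor,other,3.3
Andrena chrysosceles,Apiaceae,45.6
Andrena chrysosceles,Brassicaceae,32.1
Andrena chrysosceles,Rosaceae,14.9
Andrena chrysosceles,Malvaceae,3.1
Andrena chrysosceles,Asteraceae,2.2
Andrena chrysosceles,other,2.1
Andrena cineraria,Brassicaceae,53.8
Andrena cineraria,Apiaceae,27.9
Andrena cineraria,Rosaceae,12.9
Andrena cineraria,Rhamnaceae,3.2
Andrena cineraria,other,2.2
Andrena dorsata,Rosaceae,66.6
Andrena dorsata,Apiaceae,11.8
Andrena dorsata,Brassicaceae,9.7
Andrena dorsata,Asteraceae,7.3
Andrena dorsata,Fabaceae,4.7
Andrena flavipes,Asteraceae,56.0
Andrena flavipes,Brassicaceae,20.1
Andrena flavipes,Fabaceae,10.5
Andrena flavipes,Rosaceae,5.1
Andrena flavipes,Apiaceae,5.0
Andrena flavipes,other,3.3
Andrena florea,Cucurbitaceae,100.0
Andrena haemorrhoa,Rosaceae,37.8
Andrena haemorrhoa,Brassicaceae,31.5
Andrena haemorrhoa,Asteraceae,14.7
Andrena haemorrhoa,Resedaceae,6.3
Andrena haemorrhoa,Caprifoliaceae,4.9
Andrena haemorrhoa,other,4.8
Andrena labiata,Caryophyllaceae,50.0
Andrena labiata,Veronicaceae,16.7
Andrena labiata,Ranunculaceae,12.5
Andrena labiata,Brassicaceae,10.8
Andrena labiata,Asteraceae,7.5
Andrena labiata,Geraniaceae,2.5
Andrena minutula,Apiaceae,56.4
Andrena minutula,Brassicaceae,23.6
Andrena minutula,Rosaceae,11.6
Andrena minutula,Asteraceae,8.0
Andrena minutula,other,0.4
Andrena minutuloides,Apiaceae,100.0
Andrena nigroaenea,Apiaceae,39.4
Andrena nigroaenea,Asteraceae,34.5
Andrena nigroaenea,Brassicaceae,14.2
Andrena nigroaenea,Ranunculaceae,6.3
Andrena nigroaenea,Resedaceae,3.1
Andrena nigroaenea,other,2.5
Andrena nitida,Brassicaceae,45.6
Andrena nitida,Apiaceae,16.3
Andrena nitida,Aceraceae,9.9
Andrena nitida,Rhamnaceae,9.1
Andrena nitida,Asteraceae,4.7
Andrena nitida,Solanaceae,3.8
Andrena nitida,Lamiaceae,3.8
Andrena nitida,Rosaceae,2.4
Andrena nitida,other,4.5
Andrena scotica,Brassicaceae,65.7
Andrena scotica,Aceraceae,19.6
Andrena scotica,Apiaceae,5.4
Andrena scotica,Rosaceae,4.2
Andrena scotica,other,5.1
Andrena semilaevis,Apiaceae,91.3
Andrena semilaevis,Brassicaceae,5.3
Andrena semilaevis,Veronicaceae,1.9
Andrena semilaevis,other,1.5
Andrena subopaca,Apiaceae,48.4
Andrena subopaca,Brassicaceae,19.3
Andrena subopaca,Rosaceae,18.2
Andrena subopaca,Veronicaceae,9.2
Andrena subopaca,Fabaceae,2.6
Andrena subopaca,other,2.3
Halictus tumulorum,Asteraceae,24.2
Halictus tumulorum,Ranunculaceae,22.2
Halictus tumulorum,Fabaceae,16.9
Halictus tumulorum,Rosaceae,13.9
Halictus tumulorum,Brassicaceae,12.4
Halictus tumulorum,Rubiaceae,6.8
Halictus tumulorum,Liliaceae,3.0
Halictus tumulorum,other,0.6
Lasioglossum albipes,Ranunculaceae,65.3
Lasioglossum albipes,Rosaceae,33.3
Lasioglossum albipes,other,1.3
Lasioglossum calceatum,Asteraceae,46.9
Lasioglossum calceatum,Brassicaceae,17.5
Lasioglossum calceatum,Rosaceae,11.3
Lasioglossum calceatum,Apiaceae,6.0
Lasioglossum calceatum,Lamiaceae,3.9
Lasioglossum calceatum,Berberidaceae,3.7
Lasioglossum calceatum,Oleaceae,3.5
Lasioglossum calceatum,Ranunculaceae,2.6
Lasioglossum calceatum,other,4.6
Lasioglossum fulvicorne,Brassicaceae,67.2
Lasioglossum fulvicorne,Rosaceae,26.9
Lasioglossum fulvicorne,Apiaceae,5.0
Lasioglossum fulvicorne,other,0.8
Lasioglossum lativentre,Fabaceae,95.3
Lasioglossum lativentre,Ranunculaceae,2.6
Lasioglossum lativentre,Asteraceae,2.1
Lasioglossum leucopus,Brassicaceae,68.1
Lasioglossum leucopus,Apiaceae,22.9
Lasioglossum leucopus,Ranunculaceae,6.3
Lasioglossum leucopus,Asteraceae,2.5
Lasioglossum leucopus,other,0.3
Lasioglossum leucozonium,Asteraceae,95.3
Lasioglossum leucozonium,Ranunculaceae,4.7
Lasioglossum malachurum,Asteraceae,73.1
Lasioglossum malachurum,Brassicaceae,9.9
Lasioglossum malachurum,Rosaceae,3.3
Lasioglossum malachurum,other,13.7
Lasioglossum morio,Brassicaceae,51.2
Lasioglossum morio,Asteraceae,15.1
Lasioglossum morio,Apiaceae,12.1
Lasioglossum morio,Caprifoliaceae,11.2
Lasioglossum morio,Rosaceae,8.4
Lasioglossum morio,other,2.1
Lasioglossum parvulum,Rosaceae,28.5
Lasioglossum parvulum,Lamiaceae,23.5
Lasioglossum parvulum,Ranunculaceae,20.2
Lasioglossum parvulum,Apiaceae,11.2
Lasioglossum parvulum,Aceraceae,9.4
Lasioglossum parvulum,Asteraceae,5.9
Lasioglossum parvulum,other,1.3
Lasioglossum pauxillum,Asteraceae,62.1
Lasioglossum pauxillum,Apiaceae,9.8
Lasioglossum pauxillum,Ranunculaceae,9.4
Lasioglossum pauxillum,Rosaceae,8.7
Lasioglossum pauxillum,Brassicaceae,3.5
Lasioglossum pauxillum,Veronicaceae,2.3
Lasioglossum pauxillum,Fabaceae,2.2
Lasioglossum pauxillum,other,2.0
Lasioglossum villosulum,Asteraceae,100.0
Lasioglossum xanthopus,Asteraceae,67.8
Lasioglossum xanthopus,Brassicaceae,32.0
Lasioglossum xanthopus,other,0.2
Lasioglossum zonulum,Rosaceae,53.6
Lasioglossum zonulum,Asteraceae,21.6
Lasioglossum zonulum,Caryophyllaceae,12.9
Lasioglossum zonulum,Ranunculaceae,6.1
Lasioglossum zonulum,Caprifoliaceae,4.3
Lasioglossum zonulum,other,1.4
Melitta tricincta,Orobanchaceae,100.0
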