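taxon_name,plankton_group,size_class,carbon_factor,energy_factor,cross_class_flag
Acartia longiremis,holoplankton,SMZ,0.453,21.595,False
Calanus spp.,holoplankton,LMZ,0.502,26.889,False
Centropages typicus,holoplankton,SMZ,0.395,21.949,False
Cladocera,holoplankton,SMZ,0.439,17.680,False
Clausocalanidae,holoplankton,SMZ,0.497,21.222,False
Clione larvae,holoplankton,LMZ,0.300,17.355,False
Copepoda nauplii,holoplankton,SMZ,0.396,24.080,False
Euphausiacea larvae,holoplankton,LMZ,0.395,13.915,False
Fritillaria borealis,holoplankton,SMZ,0.545,3.868,False
Hydrozoa,holoplankton,LMZ,0.101,7.864,False
Limacina retroversa,holoplankton,LMZ,0.333,15.955,True
Metridia longa,holoplankton,LMZ,0.510,28.549,False
Oikopleura spp.,holoplankton,LMZ,0.504,3.868,True
Oithona spp.,holoplankton,SMZ,0.465,18.691,False
Paraeuchaeta spp.,holoplankton,LMZ,0.587,25.100,False
Parasagitta elegans,holoplankton,LMZ,0.399,17.366,False
Temora longicornis,holoplankton,SMZ,0.433,18.691,False
Amphinomidae,meroplankton,SMZ,0.373,17.800,False
Asteroidea,meroplankton,LMZ,0.130,9.944,False
Bivalvia,meroplankton,SMZ,0.208,7.039,False
Bryozoa,meroplankton,SMZ,0.402,8.721,False
Cirripedia,meroplankton,SMZ,0.437,17.070,False
Gastropoda,meroplankton,SMZ,0.335,18.335,False
Ophiuroidea,meroplankton,SMZ,0.142,5.425,False
Polychaeta,meroplankton,SMZ,0.373,17.800,False
Decapoda zoea,meroplankton,LMZ,0.360,12.400,False
Fish eggs,ichthyoplankton,LMZ,0.432,22.900,False
Cod larvae,ichthyoplankton,LMZ,0.432,22.900,False
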