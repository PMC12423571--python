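species,family,seed_width_mm,iucn_status
Borassus madagascariensis,Arecaceae,67.5,Endangered
Tsebona macrantha,Sapotaceae,37.5,Near threatened
Orania longisquama,Arecaceae,37.0,Least concern
Mauloutchia heckelii,Myristicaceae,35.0,Endangered
Antiaris madagascariensis,Moraceae,32.0,NA
Satranala decussilvae,Arecaceae,32.0,Endangered
Lemurophoenix halleuxii,Arecaceae,31.5,Endangered
Noronhia populifolia,Oleaceae,28.4,Critically endangered
Beilschmiedia cryptocaryoides,Lauraceae,27.0,Data deficient
Magnistipula cerebriformis,Chrysobalanaceae,27.0,Vulnerable
Gluta tourtour,Anacardiaceae,26.5,Vulnerable
Beilschmiedia velutina,Lauraceae,26.2,Least concern
Mammea sessiliflora,Calophyllaceae,25.1,Least concern
Antiaris toxicaria,Moraceae,25.0,Least concern
Euphorbia mandravioky,Euphorbiaceae,25.0,Vulnerable
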