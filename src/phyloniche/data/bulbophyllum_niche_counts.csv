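species,section,n_A,n_B,n_C,printed_code,outgroup
B. capuronii,Bifalcula,0,4,0,B,0
B. complanatum,Bifalcula,11,0,0,A,0
B. implexum,Bifalcula,12,0,0,A,0
B. minutum,Bifalcula,0,12,0,B,0
B. sp. nov. A,Bifalcula,0,3,0,B,0
B. sp. nov. B,Bifalcula,0,0,1,C,0
B. bicoloratum,Calamaria,31,0,43,C,0
B. cirrhoglossum,Calamaria,0,4,0,B,0
B. elliotii,Calamaria,1,19,0,B,0
B. erectum,Calamaria,21,48,0,AB,0
B. hildebrandtii,Calamaria,17,0,14,AC,0
B. histrionicum,Calamaria,20,0,0,A,0
B. incurvum,Calamaria,0,0,5,C,0
B. lecouflei,Calamaria,2,3,0,AB,0
B. luteobracteatum,Calamaria,0,0,4,C,0
B. malawiense,Calamaria,0,0,2,C,0
B. obtusatum,Calamaria,1,0,9,C,0
B. occultum,Calamaria,16,18,6,BC,0
B. pervillei,Calamaria,0,18,0,B,0
B. pusillum,Calamaria,2,2,35,C,0
B. quadrifarium,Calamaria,0,11,1,B,0
B. rubrum,Calamaria,9,0,0,A,0
B. ruginosum,Calamaria,0,0,3,C,0
B. senghasii,Calamaria,1,0,0,A,0
B. sp. nov. C,Calamaria,0,7,0,B,0
B. sp. nov. D,Calamaria,0,0,1,C,0
B. sp. nov. E1,Calamaria,12,0,0,A,0
B. sp. nov. E2,Calamaria,1,0,0,A,0
B. trifarium,Calamaria,8,0,2,A,0
B. humblotii,Humblotiorchis,4,35,6,B,0
B. variegatum,Alcistachys,0,12,3,B,1
B. cardiobulbum,Inversiflorum,0,0,10,C,1
B. horizontale,Kainochilus,0,0,4,C,1
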