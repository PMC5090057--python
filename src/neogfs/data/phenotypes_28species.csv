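species,common_name,brain_volume,neocortex_volume,nr,ei,mlsp
Ailuropoda_melanoleuca,giant panda,211.80935,136.43571,1.81,-2.014,36.8
Callithrix_jacchus,marmoset,7.241,4.371,1.52,-1.627,16.5
Canis_familiaris,dog,458.273,177.753,0.63,-1.699,24
Cavia_porcellus,guinea pig,4.6718,1.5798,0.51,-2.948,12
Echinops_telfairi,lesser hedgehog tenrec,0.566,0.0515,0.1,-3.274,19
Erinaceus_europaeus,hedgehog,3.05,0.522,0.21,-2.863,11.7
Gorilla_gorilla,gorilla,470.359,341.444,2.65,-1.415,55.4
Homo_sapiens,human,1251.847,1006.525,4.1,0.152,122.5
Loxodonta_africana,elephant,3886.7,2460.1,1.72,-1.082,65
Macaca_mulatta,macaque,87.896,63.482,2.6,-1.192,40
Macropus_eugenii,wallaby,11.6637,4.3987,0.61,-2.207,15.1
Microcebus_murinus,mouse lemur,1.68,0.74,0.79,-1.985,18.2
Mus_musculus,mouse,0.48,0.12,0.32,-2.832,4
Mustela_putorius_furo,European polecat,8.8996,4.147,0.87,-2.548,11.1
Ornithorhynchus_anatinus,platypus,8.57145,4.09928,0.92,-2.219,22.6
Ovis_aries,sheep,100.332,53.793,1.16,-1.961,22.8
Pan_troglodytes,chimpanzee,382.103,291.592,3.22,-0.948,59.4
Papio_anubis,olive baboon,190.957,140.142,2.76,-1.178,37.5
Pongo_abelii,orangutan,304.2,219.8,2.6,-0.892,59
Procavia_capensis,hyrax,12.68,5.54,0.78,-2.255,14.8
Pteropus_vampyrus,megabat,8.89,3.61,0.68,-2.204,20.9
Rattus_norvegicus,rat,1.69,0.58,0.52,-2.861,5
Sarcophilus_harrisii,Tasmanian devil,15.1517,3.7334,0.33,-2.792,13
Sorex_araneus,shrew,0.188,0.0264,0.16,-2.832,3.2
Sus_scrofa,pig,106.660,54.3913,1.04,-2.468,27
Tarsius_syrichta,tarsier,3.393,1.768,1.09,-1.795,16
Tursiops_truncatus,dolphin,1376.976,1088.615,3.78,-0.321,51.6
Vicugna_pacos,alpaca,181.467,101.81,1.28,-1.688,25.8
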