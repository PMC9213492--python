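rank,species,common_name,introduction_year,index_printed,colonization,prevalence
1,Cyprinus carpio,Common carp,1500,359.60,17.50,20.55
2,Oncorhynchus mykiss,Rainbow trout,1880,184.91,6.21,29.77
3,Pseudorasbora parva,Topmouth gudgeon,1980,172.34,18.03,9.56
4,Carassius auratus,Goldfish,1900,154.46,18.50,8.35
5,Silurus glanis,Wels catfish,1950,150.77,8.99,16.78
6,Rhodeus sericeus,Amur bitterling,1990,132.90,14.62,9.09
7,Gambusia holbrooki,Mosquitofish,1930,76.81,5.31,14.46
8,Lepomis gibbosus,Pumpkinseed,1880,67.51,10.15,6.65
9,Abramis brama,Common bream,1970,65.02,4.78,13.59
10,Ameiurus melas,Black bullhead,1880,56.28,3.89,14.48
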