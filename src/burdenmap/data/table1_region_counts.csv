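region,interviewed_2005,symptoms_2005,untreated_2005,interviewed_2016,symptoms_2016,untreated_2016
Tigray,1257,14,10,1682,19,4
Afar,789,5,3,1128,6,1
Amhara,1943,8,1,1719,12,9
Oromia,2230,20,17,1892,4,1
Somali,669,1,1,1391,5,1
Benishangul Gumuz,846,4,3,1126,7,4
SNNP,2087,26,19,1849,6,2
Gambella,729,5,1,1035,3,2
Harari,844,1,1,906,0,0
Addis Ababa,1869,14,7,1824,7,4
Dire Dawa,807,5,4,1131,1,0
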