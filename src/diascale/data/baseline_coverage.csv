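country,region,improved_water,treated_water,improved_sanitation,handwashing,ors,antibiotics_dysentery,zinc,rotavirus,vitamin_a
Afghanistan,Asia,48,4,37,17,30,16,0,0,96
Angola,Africa,50,20,57,17,40,20,0,0,82
Azerbaijan,Asia,80,50,45,17,10,5,0,0,90
Bangladesh,Asia,80,6,51,17,77,22,23,0,97
Benin,Africa,75,12,12,17,23,12,0,0,52
Bolivia,Other,86,77,25,17,29,31,0,0,45
Botswana,Africa,95,62,60,17,49,24,0,0,15
Brazil,Other,97,91,80,17,56,25,0,71,0
Burkina Faso,Africa,76,4,11,17,17,31,0,0,100
Burundi,Africa,72,6,46,17,38,26,0,0,80
Cambodia,Asia,61,16,29,17,21,12,0,0,88
Cameroon,Africa,74,15,47,17,13,38,0,0,92
CAR,Africa,67,2,34,17,17,39,0,0,68
Chad,Africa,50,5,9,17,15,12,0,0,0
China,Asia,89,83,55,13,29,33,0,0,0
Congo,Africa,71,28,30,17,18,22,0,0,10
Cote d'Ivoire,Africa,80,40,23,17,14,19,0,0,90
Djibouti,Africa,92,72,56,17,49,43,0,0,86
Democratic People's Republic of Korea,Asia,100,77,59,17,35,33,0,0,85
Democratic Republic of the Congo,Africa,46,9,23,17,31,21,0,0,98
Egypt,Africa,99,92,94,17,34,73,1,0,68
Equatorial Guinea,Africa,43,6,51,17,36,18,0,0,0
Eritrea,Africa,61,9,14,17,45,22,0,0,49
Ethiopia,Africa,38,7,12,17,20,5,0,0,88
Gabon,Africa,87,43,33,17,25,24,0,0,0
Gambia,Africa,92,33,67,17,41,61,0,0,28
Ghana,Africa,82,17,13,3,45,33,0,0,24
Guatemala,Other,94,81,81,17,30,15,0,0,20
Guinea,Africa,71,10,19,17,33,17,0,0,94
Guinea-Bissau,Africa,61,9,21,17,26,42,0,0,66
Haiti,Other,63,12,17,17,40,5,0,0,34
India,Asia,88,22,31,42,26,13,0,0,53
Indonesia,Asia,80,23,52,17,35,33,0,0,86
Iraq,Asia,79,76,73,17,31,82,0,0,0
Kenya,Africa,59,19,31,17,29,22,0,0,27
Laos,Asia,57,20,53,17,31,52,0,0,69
Lesotho,Africa,85,19,12,17,42,27,0,0,38
Liberia,Africa,68,2,17,17,53,49,0,0,85
Madagascar,Africa,41,7,11,4,12,20,0,0,97
Malawi,Africa,80,7,56,17,63,30,0,0,95
Mali,Africa,56,12,36,17,14,7,0,0,97
Mauritania,Africa,49,22,26,17,22,24,0,0,87
Mexico,Other,94,87,85,17,4,15,0,0,63
Morocco,Africa,81,58,69,17,23,17,0,0,43
Mozambique,Africa,47,8,17,17,49,15,0,0,83
Myanmar,Asia,71,6,81,17,45,18,0,0,94
Nepal,Asia,92,19,32,17,29,25,0,0,93
Niger,Africa,48,7,9,17,18,9,0,0,92
Nigeria,Africa,58,6,32,17,18,46,0,0,74
Pakistan,Asia,90,33,45,17,41,50,0,0,97
Peru,Other,82,70,68,14,28,28,0,0,0
Philippines,Asia,91,48,76,17,42,36,0,0,86
Papua New Guinea,Asia,40,10,45,17,30,30,0,0,7
Rwanda,Africa,65,4,54,17,21,13,0,0,76
Senegal,Africa,69,38,51,23,15,20,0,0,90
Sierra Leone,Africa,49,6,13,17,52,45,0,0,12
Somalia,Africa,30,19,23,17,9,32,0,0,100
South Africa,Africa,91,67,77,17,40,32,0,0,39
Sudan,Africa,57,28,34,17,58,45,0,0,67
Swaziland,Africa,69,32,55,17,86,24,0,0,44
Tajikistan,Asia,70,40,94,17,48,41,0,0,na
Tanzania,Africa,54,8,24,13,54,22,0,0,93
Togo,Africa,60,6,12,17,11,26,0,0,64
Turkmenistan,Asia,71,45,95,17,47,50,0,0,0
Uganda,Africa,64,3,47,14,40,47,0,0,67
Yemen,Asia,62,28,52,17,33,38,0,0,47
Zambia,Africa,60,14,49,17,60,14,0,0,96
Zimbabwe,Africa,82,36,44,17,6,8,0,0,20
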