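canonical_name,carbons,double_bonds,prefix,biomarker_class
8:0,8,0,none,none
10:0,10,0,none,none
2-OH 10:0,10,0,2-OH,none
12:0,12,0,none,none
14:0,14,0,none,none
14:1,14,1,none,none
15:0,15,0,none,none
a15:0,15,0,anteiso,bacterial
i15:0,15,0,iso,bacterial
16:0,16,0,none,none
i16:0,16,0,iso,bacterial
16:1w5,16,1,none,bacterial
16:1w7,16,1,none,bacterial
17:0,17,0,none,none
cy17:0,17,0,cyclo,bacterial
i17:0,17,0,iso,bacterial
17:1w8,17,1,none,none
18:0,18,0,none,none
18:1w7,18,1,none,bacterial
18:1w9,18,1,none,plant_relative
"18:2w6,9",18,2,none,fungal_relative
19:0,19,0,none,none
cy19:0,19,0,cyclo,bacterial
20:1w9,20,1,none,none
"20:2w6,9",20,2,none,none
20:3w6,20,3,none,none
20:4w6,20,4,none,none
20:5w3,20,5,none,none
22:1w9,22,1,none,none
22:2,22,2,none,none
23:0,23,0,none,none
24:1,24,1,none,none
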