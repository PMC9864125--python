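code,party_no,species,additive_oil,other_additives,product_weight_g,package_type
D-C-1,20848E,Tuna,Sunflower oil,Salt,80,Can
D-D-1,19/10/2020,Yellowfin Tuna,Olive oil,Salt,75,Can (BPA free)
D-D-2,07-09-2020,Skipjack,"Sunflower oil, Canola oil",Salt,80,Can
D-D-3,05-10-2020,Yellowfin Tuna,None,Water,75,Can (BPA free)
D-D-4,16.11.2024,Norwegian Salmon,Olive oil,Salt,100,Aluminum
D-D-5,10-06-2023,Skipjack,Olive oil,Salt,125,Aluminum
D-D-6,23.09.2024,Blacksea Anchovy,Sunflower oil,Salt,110,Aluminum
D-D-7,19-10-2024,Mackerel,Olive oil,Salt,110,Aluminium
D-D-8,27.01.2022,Norwegian Salmon,Olive oil,"Lemon Water, Salt",85,C/PP
D-D-9,20.10.2022,Skipjack,Sunflower oil,Salt,120,C/PP
D-D-10,18-03-2023,Yellowfin Tuna,None,Water,120,C/PP
D-D-12,25.09.2023,Skipjack,Olive oil,Salt,185,Glass
D-DE-1,20861E,Tuna,Sunflower oil,Salt,160,Can
D-MI-1,20860E CO,Tuna,Sunflower oil Canola oil,Salt,160,Can
D-W-1,20861E CO,Tuna,Sunflower oil,Salt,160,Can
I-M-1,25,Tuna,None,"Water, salt",80,Can
I-M-2,26,Skipjack,Sunflower oil (%25),"Water, salt",80,Can
I-M-3,46,Yellowfin Tuna,Olive oil (%25),"Water, salt",160,Can
I-Y-1,20,Tuna,Sunflower oil (%25),"Water, Salt",104,Can
I-Y-2,14,Mackerel,Sunflower oil,"Water, Salt",160,Aluminum
K-SF-1,0265,Tuna,Olive oil (%25),"Water, salt",75,Can
K-SF-2,0051,Tuna,Sunflower oil (%27),"Water,salt",80,Can
K-SF-3,0197,Tuna,Sunflower oil,"Water,salt",80,Can
K-SF-4,7339,Tuna,None,"Water,salt",80,Can
K-V-1,0346,Tuna,Sunflower oil,"Water, Salt",160,Can
O-F-1,L1720,Tuna,Sunflower oil,Salt,160,Can
P-P-1,9283,Tuna,None,"Water, salt",160,Can
P-P-2,20842E,Tuna,Sunflower oil (%27),"Water, salt",80,Can
S-SAS-1,302507280,Salmon,Sunflower oil,"Water,salt",160,Can
S-SAS-2,435375812,Tuna,None,"Water, Salt",160,Can
S-SAS-3,3021078T3,Tuna,Olive oil,Salt,160,Can
S-SAS-4,406009812,Tuna,Sunflower oil,"Salt,Water",80,Can
T-T-1,17848E,Tuna,Sunflower oil,Salt,80,Can
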