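shape,polymer,share_pct
fiber,Chitin,18.18
fiber,Poly(vinyl acetate),18.18
fiber,"Polyamide - Nylon 6, 6",18.18
fiber,Cellulose,9.09
fiber,Ethylene-vinyl acetate,9.09
fiber,Polyacrylonitrile,9.09
fiber,Polypropylene,9.09
fiber,Polyvinylidene chloride,9.09
fragment,Polyolefin,26.42
fragment,Poly(methacrylic acid methyl ester),11.32
fragment,Polyacrylonitrile,11.32
fragment,Polyethylene Terephthalate,9.43
fragment,Polyethylene,7.55
fragment,Polypropylene,7.55
fragment,Polystyrene,7.55
fragment,"Polyamide - Nylon 6, 6",5.66
fragment,Polyvinylidene chloride,5.66
fragment,Epoxy,3.77
fragment,Poly(vinyl acetate),3.77
total,Polyolefin,21.88
total,Polyacrylonitrile,10.94
total,Poly(methacrylic acid methyl ester),9.38
total,Polypropylene,7.81
total,Polyethylene Terephthalate,7.81
total,"Polyamide - Nylon 6, 6",7.81
total,Polyvinylidene chloride,6.25
total,Polystyrene,6.25
total,Polyethylene,6.25
total,Poly(vinyl acetate),6.25
total,Epoxy,3.13
total,Chitin,3.13
total,Ethylene-vinyl acetate,1.56
total,Cellulose,1.56
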