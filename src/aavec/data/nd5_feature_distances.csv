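,Human,Gorilla,P.chim,C.chim,F.whale,B.whale,Rat,Mouse,Opossum
Human,0,0.53,0.497,0.501,0.764,0.782,0.901,0.945,0.972
Gorilla,,0,0.522,0.564,0.755,0.803,0.876,0.963,1.025
P.chim,,,0,0.381,0.743,0.742,0.88,0.913,0.922
C.chim,,,,0,0.766,0.773,0.903,0.949,0.981
F.whale,,,,,0,0.347,0.868,0.906,1.012
B.whale,,,,,,0,0.914,0.898,0.990
Rat,,,,,,,0,0.74,0.955
Mouse,,,,,,,,0,0.859
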