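,Human,Gorilla,P.chim,C.chim,F.whale,B.whale,Rat,Mouse,Opossum
Human,0,10.7,7.1,6.9,41.0,41.3,50.2,48.9,50.4
Gorilla,,0,9.7,9.9,42.7,42.4,51.4,49.9,54.0
P.chim,,,0,5.1,40.1,40.1,50.2,48.9,50.1
C.chim,,,,0,40.4,40.4,50.8,49.6,51.4
F.whale,,,,,0,3.5,45.3,46.8,52.7
B.whale,,,,,,0,45.0,45.9,52.7
Rat,,,,,,,0,25.9,54.0
Mouse,,,,,,,,0,50.8
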