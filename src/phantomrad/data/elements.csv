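symbol,atomic_number,atomic_weight
H,1,1.008
C,6,12.011
N,7,14.007
O,8,15.999
Na,11,22.98977
Mg,12,24.305
Al,13,26.981538
Si,14,28.085
P,15,30.973762
S,16,32.06
Cl,17,35.45
K,19,39.0983
Ca,20,40.078
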