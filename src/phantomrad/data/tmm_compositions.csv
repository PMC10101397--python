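material,element,weight_fraction
skin,Na,0.004821033
skin,Cl,0.007692516
skin,C,0.275323873
skin,H,0.098487258
skin,O,0.613573165
skin,N,0.000102156
adipose,Na,0.000832225
adipose,Cl,0.004552743
adipose,C,0.689825033
adipose,H,0.12133871
adipose,O,0.17621494
adipose,K,0.003605935
adipose,Si,0.003630414
fibroglandular,Cl,0.002619926
fibroglandular,C,0.218820618
fibroglandular,H,0.105858707
fibroglandular,O,0.659929689
fibroglandular,K,0.002477372
fibroglandular,N,0.000147657
fibroglandular,Si,0.002646044
fibroglandular,Al,0.007499987
pectoral_muscle,Cl,0.000234935
pectoral_muscle,C,0.16631
pectoral_muscle,H,0.096804967
pectoral_muscle,O,0.73072
pectoral_muscle,N,0.005929387
carcinoma,Na,0.002849483
carcinoma,Cl,0.005615315
carcinoma,C,0.116584436
carcinoma,H,0.098753539
carcinoma,O,0.776084016
carcinoma,K,0.001031131
carcinoma,N,0.000113212
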