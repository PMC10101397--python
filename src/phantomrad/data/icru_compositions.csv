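material,element,weight_fraction
skin,Na,0.001
skin,Cl,0.003
skin,C,0.204
skin,H,0.1
skin,O,0.645
skin,K,0.001
skin,N,0.042
skin,S,0.002
skin,P,0.001
adipose,Na,0.001
adipose,Cl,0.001
adipose,C,0.598
adipose,H,0.114
adipose,O,0.278
adipose,N,0.007
adipose,S,0.001
fibroglandular,Na,0.001
fibroglandular,Cl,0.001
fibroglandular,C,0.332
fibroglandular,H,0.106
fibroglandular,O,0.527
fibroglandular,N,0.03
fibroglandular,S,0.002
fibroglandular,P,0.001
pectoral_muscle,Na,0.0008
pectoral_muscle,C,0.123
pectoral_muscle,H,0.101997
pectoral_muscle,O,0.720993
pectoral_muscle,Mg,0.002
pectoral_muscle,K,0.0002
pectoral_muscle,N,0.035
pectoral_muscle,S,0.005
pectoral_muscle,P,0.002
carcinoma,C,0.187626775
carcinoma,H,0.101419878
carcinoma,O,0.668356998
carcinoma,N,0.042596349
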