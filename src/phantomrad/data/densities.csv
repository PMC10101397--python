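tissue,mass_density
skin,1.09
adipose,0.95
fibroglandular,1.02
pectoral_muscle,1.04
carcinoma,0.44
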