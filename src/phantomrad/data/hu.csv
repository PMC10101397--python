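tissue,mean_hu,sd_hu,source,citation_tag
carcinoma,87.467,7.575,measured,
carcinoma,91.92,28.36,reference,L1
carcinoma,72.5,5,reference,L2
carcinoma,65.94,31.5,reference,L3
adipose,-55,23.445,measured,
adipose,-108.75,17.2,reference,L3
adipose,-68.7,2.7,reference,L2
fibroglandular,60.033,4.414,measured,
fibroglandular,65.2,6,reference,L2
fibroglandular,46.88,23.9,reference,L3
pectoral_muscle,62.367,10.334,measured,
pectoral_muscle,52.25,25.6,reference,L3
skin,132.493,4.45,measured,
skin,100.75,28.9,reference,L3
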