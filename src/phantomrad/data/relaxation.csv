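tissue,field_T,t1_s,t2_s,source
adipose,0.5,0.131,0.082,measured
pectoral_muscle,0.5,0.586,0.053,measured
skin,0.5,0.172,0.073,measured
fibroglandular,0.5,0.819,0.051,measured
carcinoma,0.5,0.569,0.058,measured
adipose,0.5,0.102,0.08,literature
pectoral_muscle,0.5,0.56,0.034,literature
skin,0.5,,,none
fibroglandular,0.5,,,none
carcinoma,0.5,,,none
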