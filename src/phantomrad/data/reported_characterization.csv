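tissue,role,ne,ne_error_pct,zeff,zeff_error_pct
skin,phantom,3.59776E+23,0.163,7.22,0.558
skin,reference,3.60362E+23,,7.2630298,
fibroglandular,phantom,3.39E+23,0.0315,7.33,5.76
fibroglandular,reference,3.17967E+23,,6.93,
adipose,phantom,3.19937E+23,0.619,6.391046106,0.956
adipose,reference,3.17967E+23,,6.330516684,
pectoral_muscle,phantom,3.43E+23,0.00415,0.829,0.195
pectoral_muscle,reference,3.44E+23,,0.8184042,
carcinoma,phantom,3.57E+23,2.93,7.46,4.46
carcinoma,reference,3.31E+23,,7.11,
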