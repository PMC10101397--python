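material,component,grams
skin,Deionized water,360
skin,X-100 surfactant,20
skin,PVA,40
skin,Benzalkonium chloride,2
skin,Sugar,240
skin,Safflower oil,80
adipose,NaCl,0.5
adipose,Deionized water,27.5
adipose,X-100 surfactant,25
adipose,Safflower oil,66
adipose,Olive oil,12.5
adipose,Beeswax,100
adipose,Agar,1.75
adipose,KCl,1
fibroglandular,SiC,1
fibroglandular,Deionized water,165.95
fibroglandular,X-100 surfactant,10
fibroglandular,Safflower oil,42.5
fibroglandular,Glycerol,32.5
fibroglandular,Agar,6.75
fibroglandular,Aluminum oxide,3.75
fibroglandular,KCl,1
fibroglandular,Benzalkonium chloride,1.25
carcinoma,NaCl,1.75
carcinoma,Agar,8.75
carcinoma,Sugar,55
carcinoma,Deionized water,175
carcinoma,Benzalkonium chloride,0.875
carcinoma,KCl,0.475
pectoral_muscle,Agar,12
pectoral_muscle,Sugar,180
pectoral_muscle,Deionized water,436.5
pectoral_muscle,Benzalkonium chloride,2.5
pectoral_muscle,X-100 surfactant,10
pectoral_muscle,Safflower oil,40
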