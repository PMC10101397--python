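name,formula,notes
Deionized water,H2O,
Sugar,C12H22O11,sucrose
NaCl,NaCl,sodium chloride
KCl,KCl,potassium chloride
SiC,SiC,silicon carbide
Aluminum oxide,Al2O3,
Glycerol,C3H8O3,
Agar,C14H24O9,agarobiose repeat-unit surrogate
PVA,C2H4O,poly(vinyl alcohol) repeat unit
X-100 surfactant,C14H22O(C2H4O)9.5,octylphenol ethoxylate average formula
Benzalkonium chloride,C21H38NCl,C12 alkyl homolog surrogate
Safflower oil,C57H98O6,trilinolein surrogate
Olive oil,C57H104O6,triolein surrogate
Beeswax,C46H92O2,triacontanyl palmitate surrogate
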