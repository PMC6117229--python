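# Most-abundant-isotope exact masses in Da (CODATA/AME-derived values, >=6 decimals)
# symbol	mass
H	1.0078250319
C	12.0000000000
N	14.0030740052
O	15.9949146221
F	18.9984031630
Na	22.9897692809
Mg	23.9850417000
Al	26.9815386300
Si	27.9769265325
P	30.9737616300
S	31.9720710015
Cl	34.9688527100
K	38.9637066800
Ca	39.9625909800
Ti	47.9479463000
Cr	51.9405075000
Mn	54.9380451000
Fe	55.9349375000
Co	58.9331950000
Ni	57.9353429000
Cu	62.9295975000
Zn	63.9291422000
Ga	68.9255736000
Ge	73.9211778000
As	74.9215965000
Se	79.9165213000
Br	78.9183371000
Sr	87.9056121000
Ag	106.9050970000
Cd	113.9033585000
In	114.9038780000
Sn	119.9021947000
Sb	120.9038157000
Te	129.9062244000
I	126.9044730000
Ba	137.9052470000
Pt	194.9647911000
Au	196.9665687000
Hg	201.9706430000
Tl	204.9744275000
Pb	207.9766521000
Bi	208.9803987000
B	11.0093054000
Li	7.0160045500
Be	9.0121822000
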