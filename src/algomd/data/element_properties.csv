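# Element-level atomic properties.
# polarizability: static dipole polarizability, A^3 (CRC Handbook / Miller-Savchik compilations)
# electronegativity: Pauling scale (dimensionless)
# hardness: absolute (Pearson) hardness eta = (IP - EA)/2, eV
symbol,polarizability,electronegativity,hardness
H,0.6668,2.20,6.43
Li,24.33,0.98,2.39
Be,5.60,1.57,4.50
B,3.03,2.04,4.01
C,1.76,2.55,5.00
N,1.10,3.04,7.23
O,0.802,3.44,6.08
F,0.557,3.98,7.01
Na,24.11,0.93,2.30
Mg,10.60,1.31,3.90
Al,6.80,1.61,2.77
Si,5.38,1.90,3.38
P,3.63,2.19,4.88
S,2.90,2.58,4.14
Cl,2.18,3.16,4.68
K,43.40,0.82,1.92
Ca,22.80,1.00,4.00
Zn,5.75,1.65,4.94
As,4.31,2.18,4.50
Se,3.77,2.55,3.87
Br,3.05,2.96,4.22
I,5.35,2.66,3.69
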