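# Per-residue Gibbs free-energy contributions for insertion at the
# dodecane-water interface (kJ/mol), from GROMOS53a6/SPC-E alchemical MD of
# single amino acids, with MD uncertainties.
# hydropathy: binary partition used by the C1/C2 neighbour classification.
# turn_propensity: Chou-Fasman beta-turn conformational parameter P(turn)
# (dimensionless); override this column to use a different turn scale.
code,name3,dg_kjmol,dg_unc_kjmol,hydropathy,turn_propensity
D,Asp,-388.14,2.87,polar,1.46
E,Glu,-356.40,0.82,polar,0.74
K,Lys,-294.61,2.34,polar,1.01
R,Arg,-270.66,1.31,polar,0.95
Y,Tyr,-177.30,2.22,polar,1.14
W,Trp,-168.78,1.69,nonpolar,0.96
G,Gly,-166.48,0.76,nonpolar,1.56
Q,Gln,-166.19,1.15,polar,0.98
H,His,-165.46,1.71,polar,0.95
A,Ala,-164.27,1.61,nonpolar,0.66
N,Asn,-161.24,2.19,polar,1.56
L,Leu,-158.99,1.58,nonpolar,0.59
V,Val,-157.54,1.74,nonpolar,0.50
F,Phe,-157.47,1.18,nonpolar,0.60
I,Ile,-156.90,1.23,nonpolar,0.47
C,Cys,-151.74,1.16,nonpolar,1.19
S,Ser,-150.28,0.98,polar,1.43
T,Thr,-146.34,0.72,polar,0.96
P,Pro,-144.78,1.05,nonpolar,1.52
M,Met,-138.63,1.58,nonpolar,0.60
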