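# Dimensionless per-residue, per-class scale factors of the group-contribution
# model: each residue contributes dG_i / alpha_(i,cls), where cls is C1 when
# the following residue shares its hydropathy and C2 when it does not.
code,cls,alpha
A,C1,8.42
A,C2,7.69
C,C1,0.77
C,C2,0.70
D,C1,5.35
D,C2,4.89
E,C1,5.24
E,C2,4.78
F,C1,4.66
F,C2,4.26
G,C1,8.60
G,C2,7.84
H,C1,2.78
H,C2,2.53
I,C1,2.87
I,C2,2.62
K,C1,4.98
K,C2,4.54
L,C1,1.74
L,C2,1.59
M,C1,4.92
M,C2,4.49
N,C1,3.85
N,C2,3.51
P,C1,9.16
P,C2,8.36
Q,C1,1.87
Q,C2,1.70
R,C1,8.30
R,C2,7.57
S,C1,5.58
S,C2,5.09
T,C1,3.57
T,C2,3.25
V,C1,8.22
V,C2,7.50
W,C1,2.52
W,C2,2.52
Y,C1,6.59
Y,C2,6.59
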