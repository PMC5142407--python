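# Gibbs free-energy contributions (kJ/mol) of the twenty alanine-based
# dipeptides (Ala-X) at the dodecane-water interface, with MD uncertainties.
base,partner,dg_kjmol,dg_unc_kjmol
A,D,-413.69,4.03
A,E,-384.85,2.06
A,K,-373.32,2.42
A,R,-255.87,1.31
A,N,-235.97,8.07
A,Y,-229.80,2.17
A,H,-220.27,3.65
A,G,-219.52,1.11
A,C,-218.76,2.70
A,L,-218.45,0.77
A,A,-218.35,1.49
A,Q,-217.31,1.47
A,P,-215.99,0.79
A,V,-215.68,0.84
A,I,-215.08,0.95
A,S,-213.13,1.20
A,F,-210.77,1.56
A,W,-209.80,1.54
A,M,-207.59,3.60
A,T,-206.68,1.63
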