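# Reference set: the twenty-one MD-simulated peptides (and the OmpA porin,
# sequence not tabulated here) used to calibrate and validate the
# group-contribution model. dg_simulated_kjmol is the alchemical-MD value in
# the dodecane-water box; dg_calculated_kjmol is the model value reported
# alongside it; relative_error_pct the published magnitude of Eq.-style
# relative error between the two.
id,sequence,dg_simulated_kjmol,dg_calculated_kjmol,relative_error_pct
p1,PVVAPAPAPAPEVQTKH,-489.5,-541.3,10.6
p2,QRAALIDCLAPDRRV,-802.8,-889.0,10.7
p3,YQWTNNIGDAHTIG,-647.6,-681.9,5.3
p4,PKDNTWYTGAKLG,-589.8,-681.9,15.6
p5,GKNHDTGVSPVFA,-903.2,-454.9,49.6
p6,MLSLGVSYRFGQG,-480.5,-553.0,15.1
p7,THENQLGAGAFG,-554.1,-530.4,4.3
p8,GAGAFGGYQVNP,-328.2,-360.8,9.9
p9,TRPDNGMLSLGV,-519.0,-519.6,0.1
p10,ALIDCLAPDRR,-517.8,-725.8,40.2
p11,IATRLEYQWTN,-525.9,-601.7,14.4
p12,TGNTCDNVKQR,-600.9,-667.1,11.0
p13,KLGWSQYHDT,-501.6,-564.9,12.6
p14,SVVVLGYTDR,-500.3,-372.7,25.5
p15,QRAALIDCLA,-740.9,-715.0,3.5
p16,DPKDGSVVVL,-604.1,-435.0,28.0
p17,NNNGPTHENQLGAGAFGGYQV,-766.7,-863.6,12.6
p18,IYTRLGGMVWRADTKSNVYGKNHDTGVSPVFAGGV,-1295.4,-1282.8,1.0
p19,WRADTKSNVYGKNHDTGVSPVFAGGV,-805.0,-941.9,17.0
p20,AHTIGTRPDNGMLSLGVSY,-607.7,-777.1,27.9
p21,VVVLGYTDRIGSDAYNQGLSERRAQSVVDYLI,-1268.0,-1427.3,12.6
OmpA,,-8561.7,-14821.8,73.1
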