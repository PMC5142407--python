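# Model constants.
# The folding correction (kJ/mol) is correction_slope * r - correction_intercept,
# applied only when the position/turn-propensity Pearson correlation r exceeds
# pearson_threshold. kB in kJ/(mol K); T_default in K (NPT setting of the
# underlying simulations).
pearson_threshold: 0.40
correction_slope: 292.8
correction_intercept: 86.6
kB: 0.0083144621
T_default: 300.0
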