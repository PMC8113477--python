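# Variant IRI activity fixture. Activity calls (active <=> mga_ratio < 0.8)
# are transcribed from the published dose-response comparison of the parent
# cyclic peptide and its mutants; the numeric mga_ratio values themselves are
# representative synthetic stand-ins consistent with those calls, since the
# underlying per-point numbers are only published as a figure.
variant_id,substitutions,redox_state,concentration,mga_ratio
peptide8,,oxidized,0.25,0.88
peptide8,,oxidized,0.5,0.46
peptide8,,oxidized,1.0,0.21
peptide8_reduced,,reduced,1.0,0.97
T4S,T4S,oxidized,1.0,0.35
T10S,T10S,oxidized,1.0,0.95
T14S,T14S,oxidized,1.0,0.99
all_thr_ser,T4S;T10S;T14S,oxidized,1.0,1.01
D8S,D8S,oxidized,1.0,0.93
scramble,G1T;T4G;D8T;G9D;T10G,oxidized,1.0,1.02
C3S_C13S,C3S;C13S,oxidized,1.0,0.98
C2S_C7S,C2S;C7S,oxidized,1.0,0.24
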