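# Cbeta 13C chemical shifts of the four cysteines (measured values as
# published). Rows marked source=synthetic are filler for non-Cys residues so
# that table-level plumbing can be exercised; they carry no measured meaning.
position,residue,atom,shift_ppm,source
2,C,CB,28.13,measured
3,C,CB,38.84,measured
7,C,CB,28.12,measured
13,C,CB,42.07,measured
4,T,CB,69.50,synthetic
8,D,CB,40.90,synthetic
10,T,CB,69.80,synthetic
14,T,CB,69.20,synthetic
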