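# Digestive proteases and the residues after which they cleave (P1 side).
# Pepsin's set includes D (aspartic acid); some printed specificity lists
# abbreviate it ambiguously ("Aps"), read here as Asp.
- name: pepsin
  c_term_residues: [D, E, L, F, W, Y]
- name: chymotrypsin
  c_term_residues: [F, W, Y]
- name: elastase
  c_term_residues: [A, G, I, L, S, V]
- name: prolyl endopeptidase
  c_term_residues: [P]
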