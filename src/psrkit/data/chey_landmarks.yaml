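# Reference landmark fixture: Escherichia coli CheY (UniProt P0AE67), the
# model receiver domain whose residue numbering anchors all positional output.
# The five conserved active-site residues: the acidic metal-binding pair
# (DD1, DD2), the Asp phosphorylation site (D), the conserved Ser/Thr (T),
# and the conserved Lys (K), given in ungapped 1-based residue numbers.
reference_id: CheY_ECOLI
sequence: >-
  MADKELKFLVVDDFSTMRRIVRNLLKELGFNNVEEAEDGVDALNKLQAGGYGFVISDWNM
  PNMDGLELLKTIRADGAMSALPVLMVTAEAKKENIIAAAQAGASGYVVKPFTAATLEEKL
  NKIFEKLGM
landmarks:
  DD1: 12
  DD2: 13
  D: 57
  T: 87
  K: 109
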