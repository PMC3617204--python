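# Canonical Th2 induction: IL-4 with anti-IFN-gamma blockade.
name: th2_induction
kind: induce
lineage: Th2
doses:
  IL4_e: 1.0
  aIFNG: 1.0
t_end: 100.0
readouts: [GATA3, IL4_s]
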