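# Canonical Th1 induction: IFN-gamma + IL-12 + IL-18 with anti-IL-4 blockade.
name: th1_induction
kind: induce
lineage: Th1
doses:
  IFNG_e: 1.0
  IL12_e: 1.0
  IL18_e: 1.0
  aIL4: 1.0
t_end: 100.0
readouts: [TBET, IFNG_s]
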