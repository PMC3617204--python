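# Canonical iTreg induction: IL-2 + TGF-beta drive STAT5/SMAD3 signaling and FOXP3.
name: itreg_induction
kind: induce
lineage: iTreg
doses:
  IL2_e: 1.0
  TGFB_e: 1.0
t_end: 100.0
readouts: [FOXP3, IL10_s]
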