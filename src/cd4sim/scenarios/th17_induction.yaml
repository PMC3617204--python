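# Canonical Th17 induction: IL-6 + TGF-beta drive STAT3/SMAD3 signaling and
# RORgt-dependent IL-17 production.
name: th17_induction
kind: induce
lineage: Th17
doses:
  IL6_e: 1.0
  TGFB_e: 1.0
t_end: 100.0
readouts: [RORGT, IL17_s, STAT3_p, FOXP3]
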