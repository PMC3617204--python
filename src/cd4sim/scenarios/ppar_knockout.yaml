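# Loss-of-function: activated PPARg made signaling-dead during induction.
# Expected: higher RORgt/IL-17 in Th17, lower FOXP3 in iTreg.
name: ppar_knockout
kind: knockout
target: PPARG_a
lineages: [Th17, iTreg]
t_end: 100.0
readouts: [RORGT, IL17_s, FOXP3]
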