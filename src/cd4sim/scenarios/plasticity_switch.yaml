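# Th17 -> iTreg plasticity: induce Th17 until the cell is fully committed
# (RORgt at 95% of plateau), then clamp the agonist input and continue.
name: plasticity_switch
kind: switch
lineage: Th17
agonist_level: 2.0
t_end: 100.0
readouts: [IL17_s, STAT3_p, RORGT, FOXP3]
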