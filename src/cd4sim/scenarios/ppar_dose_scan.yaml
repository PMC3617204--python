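# Agonist dose scan in a committed Th17 cell: ascending agonist levels
# downregulate RORgt and IL-17 and upregulate FOXP3; the top dose converts
# the cell to an iTreg phenotype.
name: ppar_dose_scan
kind: scan
lineage: Th17
parameter: PIO
grid: [0.0, 0.222, 0.444, 0.667, 0.889, 1.111, 1.333, 1.556, 1.778, 2.0]
t_end: 100.0
readouts: [FOXP3, IL17_s, RORGT, STAT3_p]
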