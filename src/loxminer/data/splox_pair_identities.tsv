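gene_a	gene_b	nucleotide_identity	protein_identity
SpLOX1	SpLOX2	92.67	85.77
SpLOX6	SpLOX7	77.68	75.77
SpLOX6	SpLOX8	78.89	86.03
SpLOX7	SpLOX8	76.91	89.48
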