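# Physical constants used throughout the package, pinned in one place so
# tests can assert against them. Masses in Da (u). Natural isotope
# abundances are IUPAC representative values; the +1/+2 channel model lumps
# each heavy isotope at an integer heavy-mass-unit offset (36S is neglected,
# abundance 1.5e-4).
constant	value
mass_H1	1.00782503207
mass_C12	12.0
mass_N14	14.0030740048
mass_O16	15.9949146196
mass_S32	31.97207100
mass_proton	1.00727646688
delta_13C	1.0033548
abundance_13C	0.0107
abundance_2H	0.000115
abundance_15N	0.00364
abundance_17O	0.00038
abundance_18O	0.00205
abundance_33S	0.0075
abundance_34S	0.0425
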