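# Basic-residue alanine-scan panel. True activities are RAW initial slopes
# (pH/s), so they scale with the expressed amount of protein; the
# expression-normalized activities mirror the reported relative levels:
# R71A keeps Cl- transport (65%) but loses SO4(2-) (8%); H167A is impaired
# in both (33/30%); K205A is nearly dead (8%); K33A expresses ~2-fold lower
# yet is WT-like after normalization (raw slopes are halved with it).
kind: panel
name: alanine-panel
mutant_names: [WT, K33A, R71A, H124A, R146A, K147A, K157A, K158A, R161A, K162A, H167A, K205A, H217A]
true_activity_cl:  [5.0e-4, 2.4e-4, 3.25e-4, 4.3e-4, 5.7e-4, 4.5e-4, 4.8e-4, 4.9e-4, 4.9e-4, 4.8e-4, 1.65e-4, 3.2e-5, 4.4e-4]
true_activity_so4: [4.0e-4, 1.9e-4, 3.2e-5,  3.5e-4, 4.6e-4, 3.6e-4, 3.9e-4, 4.0e-4, 3.9e-4, 3.9e-4, 1.2e-4,  2.6e-5, 3.5e-4]
expression: [1.0, 0.5, 1.0, 0.9, 1.1, 1.0, 0.95, 1.05, 1.0, 0.9, 1.0, 0.8, 1.0]
n_replicates: 4
replicate_cv: 0.1
seed: 1
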