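# Demo pipeline: one dataset of each measurement type, fitted end to end.
seed: 1
datasets:
  - name: wt-cl-titration
    scenario: WT-Cl
    analysis: binding
    model: one
  - name: wt-nacl-photocycle
    scenario: WT-NaCl-photocycle
    analysis: photocycle
    n_exp: 3
  - name: wt-ph-trace
    scenario: WT-ph-trace
    analysis: transport
  - name: alanine-panel
    scenario: alanine-panel
    analysis: panel
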