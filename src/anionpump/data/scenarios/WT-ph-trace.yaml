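# Wild-type style pH trace: 60 s dark baseline, 120 s illumination,
# alkalization 5e-4 pH/s, mild acid drift, 1 Hz sampling.
kind: transport
name: WT-ph-trace
true_slope: 5.0e-4
drift_slope: -1.0e-4
light_on_s: 60.0
light_off_s: 180.0
duration_s: 300.0
sample_interval_s: 1.0
noise_sigma: 2.0e-4
baseline_ph: 7.0
relax_tau_s: 30.0
seed: 1
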