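# Wild-type sulfate, two-site model (Kd 1.2 / 82 mM), amplitude split 0.6.
kind: titration
name: WT-SO4-2site
model_kind: two_site
kd1_mM: 1.2
kd2_mM: 82.0
vmax1: 0.6
shift_direction: red
unbound_band: {lambda_max_nm: 545.0, sigma_nm: 45.0, amplitude: 1.0}
bound_band: {lambda_max_nm: 557.0, sigma_nm: 45.0, amplitude: 1.0}
concentrations_mM: {log_start: 0.001, log_stop: 1000.0, num: 20, include_zero: true}
wavelengths_nm: {start: 350.0, stop: 750.0, step: 1.0}
noise_sigma: 0.01
seed: 1
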