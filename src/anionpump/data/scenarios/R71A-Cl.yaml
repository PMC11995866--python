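# R71A chloride titration: weakened Cl- binding (Kd 4.5 mM), still blue-shifting.
kind: titration
name: R71A-Cl
model_kind: one_site
kd_mM: 4.5
shift_direction: blue
unbound_band: {lambda_max_nm: 548.0, sigma_nm: 45.0, amplitude: 1.0}
bound_band: {lambda_max_nm: 538.0, sigma_nm: 45.0, amplitude: 1.0}
concentrations_mM: {log_start: 0.01, log_stop: 1000.0, num: 16, include_zero: true}
wavelengths_nm: {start: 350.0, stop: 750.0, step: 1.0}
noise_sigma: 0.02
seed: 1
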