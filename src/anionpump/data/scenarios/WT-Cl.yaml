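# Wild-type chloride titration: blue shift on Cl- binding, one-site Kd 0.59 mM.
kind: titration
name: WT-Cl
model_kind: one_site
kd_mM: 0.59
shift_direction: blue
unbound_band: {lambda_max_nm: 545.0, sigma_nm: 45.0, amplitude: 1.0}
bound_band: {lambda_max_nm: 535.0, sigma_nm: 45.0, amplitude: 1.0}
concentrations_mM: {log_start: 0.01, log_stop: 1000.0, num: 16, include_zero: true}
wavelengths_nm: {start: 350.0, stop: 750.0, step: 1.0}
noise_sigma: 0.02
seed: 1
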