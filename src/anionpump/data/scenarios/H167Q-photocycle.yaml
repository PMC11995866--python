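# H167Q photocycle: O still accumulates, slowed taus 0.20/16/65 ms.
# Bleach 560 nm, L band 470 nm, O band 620 nm.
kind: photocycle
name: H167Q-photocycle
labels: [K, L, O]
tau_s: [2.0e-4, 1.6e-2, 6.5e-2]
sads:
  - positive: {lambda_max_nm: 577.0, sigma_nm: 10.0, amplitude: 0.60}
    bleach: {lambda_max_nm: 560.0, sigma_nm: 35.0, amplitude: 0.30}
  - positive: {lambda_max_nm: 470.0, sigma_nm: 28.0, amplitude: 0.70}
    bleach: {lambda_max_nm: 560.0, sigma_nm: 35.0, amplitude: 0.90}
  - positive: {lambda_max_nm: 620.0, sigma_nm: 30.0, amplitude: 0.55}
    bleach: {lambda_max_nm: 560.0, sigma_nm: 35.0, amplitude: 0.50}
wavelengths_nm: {start: 420.0, stop: 710.0, step: 10.0}
times_s: {log_start: 1.0e-5, log_stop: 4.0, num: 60}
noise_relative: 0.01
seed: 1
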