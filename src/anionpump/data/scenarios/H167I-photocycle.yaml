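# H167I photocycle: no O accumulation; bleach 570 nm, L band 470 nm.
kind: photocycle
name: H167I-photocycle
labels: [K, L, recovery]
tau_s: [1.0e-4, 1.0e-2, 5.0e-2]
sads:
  - positive: {lambda_max_nm: 578.0, sigma_nm: 10.0, amplitude: 0.60}
    bleach: {lambda_max_nm: 570.0, sigma_nm: 35.0, amplitude: 0.30}
  - positive: {lambda_max_nm: 470.0, sigma_nm: 28.0, amplitude: 0.70}
    bleach: {lambda_max_nm: 570.0, sigma_nm: 35.0, amplitude: 0.90}
  - positive: {lambda_max_nm: 620.0, sigma_nm: 30.0, amplitude: 0.0}
    bleach: {lambda_max_nm: 570.0, sigma_nm: 35.0, amplitude: 0.40}
wavelengths_nm: {start: 420.0, stop: 710.0, step: 10.0}
times_s: {log_start: 1.0e-5, log_stop: 4.0, num: 60}
noise_relative: 0.01
seed: 1
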