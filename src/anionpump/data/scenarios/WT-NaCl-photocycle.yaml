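# Wild-type photocycle in NaCl: K -> L -> O -> ground, taus 0.050/2.2/12 ms.
# Band positions: ground bleach 558 nm, L band 462 nm, O band 620 nm; K is a
# narrow red shoulder at 575 nm (its true spectrum is unresolved at this
# time resolution).
kind: photocycle
name: WT-NaCl-photocycle
labels: [K, L, O]
tau_s: [5.0e-5, 2.2e-3, 1.2e-2]
sads:
  - positive: {lambda_max_nm: 575.0, sigma_nm: 10.0, amplitude: 0.60}
    bleach: {lambda_max_nm: 558.0, sigma_nm: 35.0, amplitude: 0.30}
  - positive: {lambda_max_nm: 462.0, sigma_nm: 28.0, amplitude: 0.70}
    bleach: {lambda_max_nm: 558.0, sigma_nm: 35.0, amplitude: 0.90}
  - positive: {lambda_max_nm: 620.0, sigma_nm: 30.0, amplitude: 0.55}
    bleach: {lambda_max_nm: 558.0, sigma_nm: 35.0, amplitude: 0.50}
wavelengths_nm: {start: 420.0, stop: 710.0, step: 10.0}
times_s: {log_start: 1.0e-5, log_stop: 4.0, num: 60}
noise_relative: 0.01
seed: 1
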