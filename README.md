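# anionpump

Quantitative analysis for light-driven anion-pump rhodopsins — proteins of
the halorhodopsin family that use retinal photoisomerization to pump
chloride (and, in the cyanobacterial pump studied here, even divalent
sulfate) into the cell.  The package is aimed at spectroscopists and
biophysicists who characterize such pumps and their mutants with three
standard measurements, and it implements the full analysis chain for each:

1. **Photocycle kinetics** (`anionpump.photocycle`).  Flash photolysis
   yields a difference-absorbance matrix dA(lambda, t).  Under an
   irreversible sequential scheme K -> L -> O -> ground with decay times
   tau_j, the species concentrations follow the Bateman solution and

       dA(lambda, t) = sum_j SADS_j(lambda) c_j(t) = sum_i DADS_i(lambda) e^(-t/tau_i).

   `fit_global` recovers the shared taus by variable projection (amplitudes
   solved exactly at each step), converts between decay- and
   species-associated difference spectra, labels intermediates by band
   position, and scores O-intermediate accumulation — the diagnostic that
   separates wild-type-like mutants from those that skip the O state.

2. **Anion binding** (`anionpump.binding`).  Titration spectra give
   difference-spectrum curves fitted with the constrained hyperbolic
   isotherms

       dA = x/(Kd + x)                                     (one site)
       dA = Vmax1 x/(Kd1 + x) + (1 - Vmax1) x/(Kd2 + x)    (two sites)

   with the saturating amplitude fixed at 1, plus shift classification
   (blue = chloride-like, red = sulfate-like), an isosbestic-point
   two-state check, and AICc model selection.

3. **Transport activity** (`anionpump.transport`).  The initial slope of
   the light-induced extracellular pH change (0-10 s, drift-corrected) is
   the activity statistic; panels of mutants are normalized by expression
   level, tested against the wild type with a permutation maxT
   (Dunnett-style) procedure, and summarized by the Pearson correlation of
   chloride vs sulfate activities.

Every stage has a seeded synthetic-data generator
(`anionpump.synthetic`) with known ground truth, so the whole chain is
validated by parameter recovery; a catalog of scenarios planted at the
reported wild-type and mutant parameters ships with the package
(`anionpump list-scenarios`).

## Worked example

Simulate a wild-type photocycle measurement and fit it:

```sh
anionpump simulate-transient --scenario WT-NaCl-photocycle --seed 4 --out wt.csv
anionpump fit-photocycle --input wt.csv --n-exp 3 --out wt_fit.json
```

`wt_fit.json` (abridged):

```json
{
  "tau_ms": [0.0495, 2.2019, 12.0695],
  "labels": ["K", "L", "O"],
  "o_accumulating": true,
  "o_score": 0.513
}
```

The three fitted time constants are the decay times of the K, L and O
intermediates in milliseconds — the scenario planted 0.050, 2.2 and 12 ms,
so each is recovered within about 1% at the 1% noise level — and the
O-accumulation score of 0.51 (positive 590-640 nm amplitude relative to the
ground-state bleach) is far above the 0.10 decision threshold: this
photocycle forms the O state.

The binding chain works the same way:

```sh
anionpump simulate-titration --scenario WT-Cl --seed 4 --out wtcl.csv
anionpump fit-binding --input wtcl.csv --model one --out wtcl_fit.json
```

returns `"kd_mM": 0.613` for a planted chloride dissociation constant of
0.59 mM, with `"shift": "blue"` — chloride binding blue-shifts the band.

From Python, the same example is:

```python
from anionpump import binding, scenarios, synthetic

series = synthetic.gen_titration(scenarios.load_scenario("WT-Cl", seed=4))
curve = binding.extract_curve(series)
fit = binding.fit_one_site(curve)
print(fit.kd_mM)   # 0.613 (planted: 0.59)
```

## Analysis drivers

The `analysis/` scripts run the recovery studies end to end and write
tables under `results/`:

| script | what it does | output |
|---|---|---|
| `01_simulate_datasets.py` | one dataset of each measurement type | `results/data/*.csv` |
| `02_binding_affinity.py` | 20-seed Kd recovery for all titration scenarios | `results/binding_recovery.csv` |
| `03_photocycle_kinetics.py` | 20-seed tau recovery + O classification | `results/photocycle_recovery.csv` |
| `04_transport_activity.py` | panel normalization, significance, correlation | `results/transport_panel.csv`, `results/anion_correlation.json` |

`anionpump run-pipeline --config configs/demo.yaml --out demo/` exercises
the same stages through the config-driven pipeline.

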