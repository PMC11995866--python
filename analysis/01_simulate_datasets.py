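#!/usr/bin/env python
"""Generate one synthetic dataset of each measurement type.

Writes, under results/data/: a wild-type chloride titration series, a
wild-type transient-absorption matrix, a light-induced pH trace, and an
alanine-scan activity panel — each from its catalog scenario at seed 1,
in the CSV dialects the fitting stages read back.
"""

from pathlib import Path

from anionpump import io as apio
from anionpump import scenarios, synthetic

OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    jobs = [
        ("WT-Cl", synthetic.gen_titration, apio.write_titration_csv, "wt_cl_titration.csv"),
        ("WT-NaCl-photocycle", synthetic.gen_transient, apio.write_transient_csv,
         "wt_nacl_transient.csv"),
        ("WT-ph-trace", synthetic.gen_ph_trace, apio.write_ph_csv, "wt_ph_trace.csv"),
        ("alanine-panel", synthetic.gen_mutant_panel, apio.write_panel_csv,
         "alanine_panel.csv"),
    ]
    for name, gen, write, filename in jobs:
        dataset = gen(scenarios.load_scenario(name, seed=1))
        write(dataset, OUT / filename)
        print(f"{name:24s} -> results/data/{filename}")


if __name__ == "__main__":
    main()
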