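"""Seeded synthetic-data generators with known ground truth.

Each generator emulates one measurement type of the study — anion-titration
spectra, flash-photolysis transient matrices, light-driven pH traces, and
mutant activity panels — from a scenario whose parameters are the ground
truth, so every downstream fitter can be validated by parameter recovery.
All randomness flows through ``numpy.random.default_rng(scenario.seed)``;
identical scenario + seed reproduces the dataset bit for bit.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import photocycle as pc
from .binding import SpectrumSeries
from .errors import ValidationError
from .scenarios import (
    PanelScenario,
    PhotocycleScenario,
    TitrationScenario,
    TransportScenario,
)
from .transport import MutantPanel, PhTrace

__all__ = [
    "gen_titration",
    "gen_transient",
    "gen_ph_trace",
    "gen_mutant_panel",
    "gen_correlated_panel",
]


def gen_titration(scenario: TitrationScenario) -> SpectrumSeries:
    """Titration spectra: isotherm-weighted mixture of unbound and bound bands.

    At concentration ``c`` the clean spectrum is
    ``(1 - f(c)) * unbound + f(c) * bound`` with ``f`` the scenario's one- or
    two-site isotherm; homoscedastic Gaussian noise is added per cell.
    """
    wl = scenario.wavelengths_nm
    f = scenario.fraction_bound()
    unbound = scenario.unbound_band(wl)
    bound = scenario.bound_band(wl)
    A = np.outer(unbound, 1.0 - f) + np.outer(bound, f)
    if scenario.noise_sigma > 0:
        rng = np.random.default_rng(scenario.seed)
        A = A + rng.normal(0.0, scenario.noise_sigma, size=A.shape)
    anion = "SO4" if "SO4" in scenario.name.upper() else ("Cl" if "CL" in scenario.name.upper() else "")
    return SpectrumSeries(
        wavelengths_nm=wl,
        concentrations_mM=scenario.concentrations_mM,
        absorbance=A,
        anion=anion,
    )


def gen_transient(scenario: PhotocycleScenario) -> pc.TransientDataset:
    """Transient difference-absorbance matrix from the sequential chain.

    dA(lambda, t) = sum_j SADS_j(lambda) c_j(t) + noise, with c_j the Bateman
    concentrations.  ``noise_relative`` (if set) scales the noise to the
    clean matrix's maximum |dA|, emulating a fixed instrumental
    signal-to-noise ratio.
    """
    labels = scenario.labels or [str(i + 1) for i in range(len(scenario.tau_s))]
    scheme = pc.SequentialScheme(labels, scenario.tau_s)
    clean = pc.forward_model(
        scheme, scenario.sads_matrix(), scenario.wavelengths_nm, scenario.times_s
    )
    sigma = scenario.noise_sigma
    if scenario.noise_relative is not None:
        sigma = scenario.noise_relative * np.max(np.abs(clean.deltaA))
    dA = clean.deltaA
    if sigma > 0:
        rng = np.random.default_rng(scenario.seed)
        dA = dA + rng.normal(0.0, sigma, size=dA.shape)
    return pc.TransientDataset(scenario.wavelengths_nm, scenario.times_s, dA)


def gen_ph_trace(scenario: TransportScenario) -> PhTrace:
    """Extracellular pH trace: drift, a linear light-on ramp, and relaxation.

    Before illumination the trace follows a linear baseline drift; during
    illumination the true transport slope adds on top of the drift; after
    light-off the accumulated light-induced signal relaxes exponentially back
    to the drift line (the relaxation shape is irrelevant to the 0-10 s
    initial-slope statistic).
    """
    t = np.arange(0.0, scenario.duration_s + 0.5 * scenario.sample_interval_s,
                  scenario.sample_interval_s)
    ph = scenario.baseline_ph + scenario.drift_slope * t
    on, off = scenario.light_on_s, scenario.light_off_s
    lit = (t >= on) & (t <= off)
    ph[lit] += scenario.true_slope * (t[lit] - on)
    after = t > off
    amplitude = scenario.true_slope * (off - on)
    ph[after] += amplitude * np.exp(-(t[after] - off) / scenario.relax_tau_s)
    if scenario.noise_sigma > 0:
        rng = np.random.default_rng(scenario.seed)
        ph = ph + rng.normal(0.0, scenario.noise_sigma, size=ph.shape)
    return PhTrace(times_s=t, ph=ph, light_on_s=on, light_off_s=off)


def gen_mutant_panel(scenario: PanelScenario) -> MutantPanel:
    """Replicated activity panel with expression levels, WT included.

    Each replicate slope is drawn as ``true * (1 + cv * N(0,1))`` — i.e. a
    fixed coefficient of variation around the planted activity — for both the
    chloride and sulfate conditions.
    """
    rng = np.random.default_rng(scenario.seed)
    rows = []
    for i, name in enumerate(scenario.mutant_names):
        for anion, true in (
            ("Cl", scenario.true_activity_cl[i]),
            ("SO4", scenario.true_activity_so4[i]),
        ):
            noise = rng.normal(0.0, 1.0, size=scenario.n_replicates)
            slopes = true * (1.0 + scenario.replicate_cv * noise)
            for r, s in enumerate(slopes):
                rows.append({"mutant": name, "anion": anion, "replicate": r + 1, "slope": s})
    df = pd.DataFrame(rows)
    expression = dict(zip(scenario.mutant_names, scenario.expression))
    return MutantPanel(data=df, expression=expression)


def gen_correlated_panel(
    n_mutants: int = 12,
    rho: float = 0.94,
    seed: int = 0,
    wt_cl: float = 5e-4,
    wt_so4: float = 4e-4,
    spread: float = 0.35,
    n_replicates: int = 4,
    replicate_cv: float = 0.05,
) -> tuple[PanelScenario, MutantPanel]:
    """Panel whose per-mutant (Cl, SO4) activities follow a bivariate normal.

    The log-activities of ``n_mutants`` mutants are drawn with correlation
    ``rho`` on the correlated-component scale, emulating a mutant family with
    a shared transport pathway.  Returns both the planted scenario and the
    generated panel so tests can compare the recovered Pearson R with the
    generating correlation.
    """
    if not (0 < rho <= 1):
        raise ValidationError(f"rho must be in (0, 1], got {rho}")
    rng = np.random.default_rng(seed)
    cov = spread**2 * np.array([[1.0, rho], [rho, 1.0]])
    z = rng.multivariate_normal(np.zeros(2), cov, size=n_mutants - 1, method="cholesky")
    names = ["WT"] + [f"M{i + 1}" for i in range(n_mutants - 1)]
    # activities stay positive through the multiplicative (1 + z) perturbation
    cl = np.concatenate([[wt_cl], wt_cl * np.clip(1.0 + z[:, 0], 0.05, None)])
    so4 = np.concatenate([[wt_so4], wt_so4 * np.clip(1.0 + z[:, 1], 0.05, None)])
    scenario = PanelScenario(
        name=f"correlated-rho{rho}",
        mutant_names=names,
        true_activity_cl=cl,
        true_activity_so4=so4,
        expression=np.ones(n_mutants),
        n_replicates=n_replicates,
        replicate_cv=replicate_cv,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    return scenario, gen_mutant_panel(scenario)
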