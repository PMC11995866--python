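"""Transport-activity statistics from light-induced pH traces.

Anion uptake by cells expressing the pump acidifies/alkalizes the medium;
the initial slope of the extracellular pH change over the first 10 s of
illumination (with the protonophore CCCP present) is the standard activity
readout.  This module computes that statistic with baseline-drift
correction, normalizes mutant panels by expression level, tests each mutant
against the wild type with a permutation maxT many-to-one procedure
(a distribution-free analogue of Dunnett's test), and quantifies the
cross-anion correlation of activities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = [
    "PhTrace",
    "ActivityResult",
    "MutantPanel",
    "CorrelationResult",
    "initial_slope",
    "normalize_panel",
    "compare_to_wt",
    "correlate_anions",
]


@dataclass(frozen=True)
class PhTrace:
    """A pH time course with light-on/off event times."""

    times_s: np.ndarray
    ph: np.ndarray
    light_on_s: float
    light_off_s: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        ph = np.asarray(self.ph, dtype=float)
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "ph", ph)
        if t.shape != ph.shape or t.ndim != 1:
            raise ValidationError("times_s and ph must be matching 1-D arrays")
        if not np.all(np.diff(t) > 0):
            raise ValidationError("times_s must be strictly ascending")
        if not t[0] <= self.light_on_s < self.light_off_s <= t[-1]:
            raise ValidationError("light events must lie within the trace and be ordered")


@dataclass(frozen=True)
class ActivityResult:
    """Initial-slope statistic of one trace (pH/s; alkalization positive)."""

    slope: float
    drift: float
    window_s: float
    raw_slope: float  # light-window OLS slope before drift subtraction
    truncated: bool = False


@dataclass(frozen=True)
class MutantPanel:
    """Replicate activity slopes per mutant and anion, plus expression levels.

    ``data`` is long-format with columns (mutant, anion, replicate, slope);
    ``expression`` maps mutant name to relative expressed protein (WT = 1).
    """

    data: pd.DataFrame
    expression: dict[str, float]

    def __post_init__(self) -> None:
        required = {"mutant", "anion", "replicate", "slope"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValidationError(f"panel data missing columns {sorted(missing)}")
        mutants = set(self.data["mutant"])
        if "WT" not in mutants:
            raise ValidationError("panel must include a WT entry")
        for m in mutants:
            if m not in self.expression:
                raise ValidationError(f"no expression level for mutant {m!r}")
            if self.expression[m] <= 0:
                raise ValidationError(f"expression must be > 0, got {self.expression[m]} for {m!r}")

    def slopes(self, mutant: str, anion: str) -> np.ndarray:
        sel = (self.data["mutant"] == mutant) & (self.data["anion"] == anion)
        return self.data.loc[sel, "slope"].to_numpy(dtype=float)


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation and OLS regression between two activity axes."""

    r: float
    slope: float
    intercept: float
    p_value: float
    n: int


def _ols_slope(t: np.ndarray, y: np.ndarray) -> float:
    return float(np.polyfit(t, y, 1)[0])


def initial_slope(
    trace: PhTrace,
    window_s: float = 10.0,
    drift_correct: bool = True,
    min_baseline_s: float = 30.0,
) -> ActivityResult:
    """Initial transport slope over [light_on, light_on + window] (pH/s).

    The pre-illumination segment provides a linear drift estimate which is
    subtracted from the light-window OLS slope (``drift_correct=False``
    returns the raw slope).  A window reaching past light-off is truncated
    with a warning; alkalization (pH increase) is positive by convention.
    """
    t, ph = trace.times_s, trace.ph
    end = trace.light_on_s + window_s
    truncated = False
    if end > trace.light_off_s:
        warnings.warn(
            f"initial-slope window {window_s} s extends past light-off; truncating",
            stacklevel=2,
        )
        end = trace.light_off_s
        truncated = True
    pre = t < trace.light_on_s
    if trace.light_on_s - t[0] < min_baseline_s:
        raise ValidationError(
            f"pre-illumination segment shorter than {min_baseline_s} s"
        )
    lit = (t >= trace.light_on_s) & (t <= end)
    if np.sum(lit) < 5:
        raise ValidationError(f"fewer than 5 samples in the initial-slope window (got {np.sum(lit)})")
    drift = _ols_slope(t[pre], ph[pre])
    raw = _ols_slope(t[lit], ph[lit])
    slope = raw - drift if drift_correct else raw
    return ActivityResult(
        slope=slope, drift=drift, window_s=end - trace.light_on_s, raw_slope=raw,
        truncated=truncated,
    )


def normalize_panel(panel: MutantPanel) -> pd.DataFrame:
    """Expression-normalized activities per (mutant, anion).

    Each replicate slope is divided by the mutant's expression level; the
    table reports mean, SD and n of the normalized replicates plus the
    activity relative to WT (WT = 1 per anion).
    """
    df = panel.data.copy()
    df["normalized"] = df.apply(
        lambda row: row["slope"] / panel.expression[row["mutant"]], axis=1
    )
    out = (
        df.groupby(["mutant", "anion"])["normalized"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
    wt = out[out["mutant"] == "WT"].set_index("anion")["mean"]
    out["relative_to_wt"] = out.apply(lambda row: row["mean"] / wt[row["anion"]], axis=1)
    return out


def compare_to_wt(
    panel: MutantPanel,
    anion: str,
    n_permutations: int = 2000,
    seed: int = 0,
    normalized: bool = True,
) -> pd.DataFrame:
    """Many-to-one comparison of every mutant against WT, permutation maxT.

    Welch t statistics are computed for each mutant vs WT; the family-wise
    null distribution is built by permuting the pooled observations across
    groups and recording the maximum |t| over the family, so the adjusted
    p-values control the family-wise error rate at the nominal level without
    distributional assumptions (the permutation analogue of Dunnett's test).
    Mutants with fewer than 3 replicates are skipped with a warning.
    """
    groups: dict[str, np.ndarray] = {}
    for mutant in sorted(set(panel.data["mutant"])):
        vals = panel.slopes(mutant, anion)
        if normalized:
            vals = vals / panel.expression[mutant]
        if mutant != "WT" and vals.size < 3:
            warnings.warn(f"skipping {mutant}: fewer than 3 replicates", stacklevel=2)
            continue
        groups[mutant] = vals
    if "WT" not in groups or groups["WT"].size < 3:
        raise ValidationError("WT needs at least 3 replicates")
    mutants = [m for m in groups if m != "WT"]
    if not mutants:
        raise ValidationError(f"no mutant with >= 3 replicates for anion {anion!r}")

    def welch_t(a: np.ndarray, b: np.ndarray) -> float:
        va, vb = a.var(ddof=1), b.var(ddof=1)
        denom = np.sqrt(va / a.size + vb / b.size)
        if denom == 0:
            return 0.0
        return float((a.mean() - b.mean()) / denom)

    observed = {m: welch_t(groups[m], groups["WT"]) for m in mutants}

    pooled = np.concatenate([groups["WT"]] + [groups[m] for m in mutants])
    sizes = [groups["WT"].size] + [groups[m].size for m in mutants]
    bounds = np.cumsum([0] + sizes)
    rng = np.random.default_rng(seed)
    # all permutations at once: argsort of uniforms is a uniform permutation
    order = np.argsort(rng.random((n_permutations, pooled.size)), axis=1)
    shuffled = pooled[order]  # (B, N)

    def _stats(block: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
        return block.mean(axis=1), block.var(axis=1, ddof=1), block.shape[1]

    m0, v0, n0 = _stats(shuffled[:, bounds[0]: bounds[1]])
    max_t = np.zeros(n_permutations)
    for i in range(len(mutants)):
        mi, vi, ni = _stats(shuffled[:, bounds[i + 1]: bounds[i + 2]])
        denom = np.sqrt(vi / ni + v0 / n0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(denom > 0, (mi - m0) / denom, 0.0)
        np.maximum(max_t, np.abs(t), out=max_t)

    rows = []
    for m in mutants:
        t_obs = observed[m]
        p_adj = (1.0 + np.sum(max_t >= abs(t_obs))) / (n_permutations + 1.0)
        rows.append(
            {
                "mutant": m,
                "anion": anion,
                "t": t_obs,
                "p_adjusted": p_adj,
                "significant": p_adj < 0.05,
            }
        )
    return pd.DataFrame(rows)


def correlate_anions(
    panel: MutantPanel, exclude: tuple[str, ...] = ()
) -> CorrelationResult:
    """Pearson correlation of per-mutant normalized Cl vs SO4 activities.

    Uses the expression-normalized per-mutant means; an optional exclusion
    list removes named mutants from both axes before correlating.
    """
    norm = normalize_panel(panel)
    wide = norm.pivot(index="mutant", columns="anion", values="mean")
    if not {"Cl", "SO4"} <= set(wide.columns):
        raise ValidationError("panel needs both 'Cl' and 'SO4' conditions")
    wide = wide.drop(index=[m for m in exclude if m in wide.index])
    wide = wide.dropna()
    if len(wide) < 3:
        raise ValidationError("need >= 3 mutants with both conditions")
    x = wide["Cl"].to_numpy(dtype=float)
    y = wide["SO4"].to_numpy(dtype=float)
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValidationError("zero variance in one axis: correlation undefined")
    r, p = stats.pearsonr(x, y)
    reg = stats.linregress(x, y)
    return CorrelationResult(
        r=float(r), slope=float(reg.slope), intercept=float(reg.intercept),
        p_value=float(p), n=len(wide),
    )
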