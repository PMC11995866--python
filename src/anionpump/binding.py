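"""Anion-titration analysis: difference spectra, shift classification,
isosbestic-point check, and constrained hyperbolic isotherm fitting.

The measurement is a series of visible absorption spectra at increasing salt
concentration.  Binding shifts the retinal band (blue for chloride, red for
sulfate in the wild-type pump), so the difference spectrum against the
salt-free reference has a positive and a negative lobe.  The absorbance
change at the dominant lobe, plotted against concentration, is fitted with

    one-site:  dA = x / (Kd + x)
    two-site:  dA = Vmax1 x / (Kd1 + x) + (1 - Vmax1) x / (Kd2 + x)

with the saturating amplitude fixed at 1, so the curve must be normalized to
its fitted plateau before the constrained fit (see :func:`extract_curve`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np

from . import isotherm
from .errors import NoSignalError, ValidationError

__all__ = [
    "SpectrumSeries",
    "TitrationCurve",
    "HillFit",
    "difference_spectra",
    "classify_shift",
    "find_isosbestic",
    "extract_curve",
    "fit_one_site",
    "fit_two_site",
    "select_model",
    "aicc",
]


@dataclass(frozen=True)
class SpectrumSeries:
    """Absorption spectra over a titration, one column per concentration.

    The first concentration is the reference (typically 0 mM salt).
    """

    wavelengths_nm: np.ndarray
    concentrations_mM: np.ndarray
    absorbance: np.ndarray
    anion: str = ""

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        c = np.asarray(self.concentrations_mM, dtype=float)
        A = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "concentrations_mM", c)
        object.__setattr__(self, "absorbance", A)
        if not np.all(np.diff(wl) > 0):
            raise ValidationError("wavelengths_nm must be strictly ascending")
        if not np.all(np.diff(c) > 0):
            raise ValidationError("concentrations_mM must be strictly ascending")
        if np.any(c < 0):
            raise ValidationError("concentrations_mM must be >= 0")
        if A.shape != (wl.size, c.size):
            raise ValidationError(
                f"absorbance shape {A.shape} does not match grids ({wl.size}, {c.size})"
            )


@dataclass(frozen=True)
class TitrationCurve:
    """Normalized absorbance change at the tracked peak wavelength vs concentration."""

    concentrations_mM: np.ndarray
    deltaA: np.ndarray
    peak_wavelength_nm: float
    anion: str = ""
    plateau: float = 1.0  # raw-units plateau the curve was divided by

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations_mM, dtype=float)
        y = np.asarray(self.deltaA, dtype=float)
        object.__setattr__(self, "concentrations_mM", c)
        object.__setattr__(self, "deltaA", y)
        if c.shape != y.shape or c.ndim != 1:
            raise ValidationError("concentrations and deltaA must be matching 1-D arrays")
        if not np.all(np.diff(c) > 0):
            raise ValidationError("concentrations_mM must be strictly ascending")


@dataclass(frozen=True)
class HillFit:
    """Result of a constrained one- or two-site isotherm fit (Kd in mM)."""

    model_kind: str
    kd_mM: float | None = None
    kd1_mM: float | None = None
    kd2_mM: float | None = None
    vmax1: float | None = None
    rss: float = np.nan
    aicc: float = np.nan
    stderr: dict = field(default_factory=dict)
    converged: bool = True
    flags: tuple[str, ...] = ()

    def predict(self, x) -> np.ndarray:
        if self.model_kind == "one_site":
            return isotherm.one_site(x, self.kd_mM)
        return isotherm.two_site(x, self.kd1_mM, self.kd2_mM, self.vmax1)


def aicc(rss: float, n: int, n_params: int) -> float:
    """Small-sample corrected Akaike criterion for a Gaussian least-squares fit.

    ``n_params`` counts the model parameters; the noise variance adds one more.
    """
    k = n_params + 1
    if n - k - 1 <= 0:
        return np.inf
    return n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


# ---------------------------------------------------------------------------
# Spectral preprocessing
# ---------------------------------------------------------------------------


def difference_spectra(series: SpectrumSeries) -> np.ndarray:
    """Each column minus the reference (first) column; reference column is zero."""
    if series.concentrations_mM.size < 2:
        raise ValidationError("need at least 2 concentrations for difference spectra")
    return series.absorbance - series.absorbance[:, [0]]


def classify_shift(diff: np.ndarray, wavelengths_nm: np.ndarray, floor: float | None = None) -> str:
    """Classify the spectral shift of the highest-concentration difference column.

    Returns ``"blue"`` if the positive lobe sits at shorter wavelength than
    the negative lobe, ``"red"`` for the converse, and ``"none"`` when the
    column's extreme value stays below a noise floor.  The default floor is
    estimated from the column's first differences (spectral bands are smooth,
    so differencing isolates the noise) as a robust sigma scaled by the
    expected extreme of ``n`` Gaussian draws plus one sigma of margin — a
    pure-noise column stays below it.
    """
    diff = np.asarray(diff, dtype=float)
    wl = np.asarray(wavelengths_nm, dtype=float)
    if diff.ndim != 2 or diff.shape[0] != wl.size or diff.shape[1] < 2:
        raise ValidationError("diff must be (n_wavelengths, >=2 columns)")
    col = diff[:, -1]
    if floor is None:
        sigma = np.median(np.abs(np.diff(col))) / (0.6745 * np.sqrt(2.0))
        floor = sigma * (np.sqrt(2.0 * np.log(col.size)) + 1.0)
    if np.max(np.abs(col)) <= floor or not np.any(col):
        return "none"
    lam_pos = wl[int(np.argmax(col))]
    lam_neg = wl[int(np.argmin(col))]
    if col.max() <= 0 or col.min() >= 0:
        return "none"  # single-signed column: no shift signature
    return "blue" if lam_pos < lam_neg else "red"


def find_isosbestic(
    diff: np.ndarray,
    wavelengths_nm: np.ndarray,
    window_nm: tuple[float, float] = (550.0, 600.0),
    tol_frac: float = 0.05,
) -> float | None:
    """Wavelength where all difference columns (nearly) vanish, or ``None``.

    A clean two-state titration pins an isosbestic point: a wavelength at
    which every concentration's difference spectrum crosses zero.  The
    candidate is the in-window wavelength minimizing the maximum |dA| across
    columns; it is reported only if that maximum stays below ``tol_frac``
    of the global |dA| maximum — otherwise the series is not two-state.
    """
    diff = np.asarray(diff, dtype=float)
    wl = np.asarray(wavelengths_nm, dtype=float)
    lo, hi = window_nm
    mask = (wl >= lo) & (wl <= hi)
    if not np.any(mask):
        raise ValidationError(f"window {window_nm} nm outside the wavelength grid")
    cross_max = np.max(np.abs(diff[mask, 1:]), axis=1) if diff.shape[1] > 1 else np.abs(diff[mask, 0])
    i = int(np.argmin(cross_max))
    tol = tol_frac * np.max(np.abs(diff))
    if cross_max[i] < tol:
        return float(wl[mask][i])
    return None


# ---------------------------------------------------------------------------
# Curve extraction and fitting
# ---------------------------------------------------------------------------


def _provisional_plateau(x: np.ndarray, y: np.ndarray, kind: str) -> tuple[float, float, int]:
    """Plateau of an unconstrained provisional fit: (vmax, rss, n_params)."""
    if kind == "one_site":
        model = lmfit.Model(lambda x, log_kd, vmax: isotherm.one_site(x, np.exp(log_kd), vmax))
        params = model.make_params(log_kd=np.log(np.median(x[x > 0])), vmax=1.2 * y.max())
        n_params = 2
    elif kind == "two_site":
        def f(x, log_kd1, log_kd2, vmax1_frac, vmax):
            return vmax * isotherm.two_site(x, np.exp(log_kd1), np.exp(log_kd2), vmax1_frac)

        model = lmfit.Model(f)
        pos = x[x > 0]
        params = model.make_params(
            log_kd1=np.log(np.quantile(pos, 0.25)),
            log_kd2=np.log(np.quantile(pos, 0.75)),
            vmax1_frac=dict(value=0.5, min=0.0, max=1.0),
            vmax=1.2 * y.max(),
        )
        n_params = 4
    else:
        raise ValidationError(f"unknown provisional model {kind!r}")
    out = model.fit(y, params, x=x)
    return float(out.params["vmax"].value), float(np.sum(out.residual**2)), n_params


def extract_curve(
    series: SpectrumSeries, provisional: str = "one_site", smooth_nm: float = 10.0
) -> TitrationCurve:
    """Track the dominant difference-spectrum lobe and normalize to its plateau.

    The tracked wavelength is the largest-|dA| lobe of the highest-
    concentration difference spectrum.  Both the peak search and the reads
    use a boxcar spectral bandwidth of ``smooth_nm`` (centered on the fixed
    tracked wavelength), emulating the finite slit width of a scanning
    spectrophotometer; this keeps the extracted point from being dominated
    by a single noisy grid cell.  The signed change at the tracked
    wavelength is read for every concentration and divided by the plateau
    of a provisional unconstrained fit, so that the subsequent constrained
    (Vmax = 1) fits are self-consistent even when the titration does not
    fully saturate.  ``provisional`` chooses the plateau model:
    ``"one_site"`` (default), ``"two_site"``, or ``"auto"`` (lower AICc).
    """
    if series.concentrations_mM.size < 4:
        raise ValidationError("need >= 4 concentrations to extract a fittable curve")
    diff = difference_spectra(series)
    scale = np.max(np.abs(diff[:, -1]))
    if scale <= 0 or not np.isfinite(scale):
        raise NoSignalError("no titratable signal: flat difference spectra")
    step = np.median(np.diff(series.wavelengths_nm))
    half = max(int(round(0.5 * smooth_nm / step)), 0)
    if half:
        kernel = np.ones(2 * half + 1) / (2 * half + 1)
        diff = np.apply_along_axis(np.convolve, 0, diff, kernel, mode="same")
    # Locate the lobes on the span between the highest and lowest nonzero
    # concentrations: the shared reference-column noise cancels there, so the
    # selected wavelengths are not the ones where the reference happened to
    # fluctuate — that same fluctuation offsets every curve point and would
    # otherwise bias the isotherm fit.
    span = diff[:, -1] - diff[:, 1] if diff.shape[1] > 2 else diff[:, -1]
    ipos, ineg = int(np.argmax(span)), int(np.argmin(span))
    x = series.concentrations_mM
    if span[ipos] > 0 and span[ineg] < 0:
        # both lobes present: their difference doubles the signal and is the
        # change "at the peak wavelengths" of the difference spectrum
        y_raw = diff[ipos, :] - diff[ineg, :]
        ipeak = ipos if span[ipos] >= -span[ineg] else ineg
    else:
        ipeak = ipos if abs(span[ipos]) >= abs(span[ineg]) else ineg
        y_raw = np.sign(span[ipeak]) * diff[ipeak, :]

    kinds = {"one_site": ("one_site",), "two_site": ("two_site",), "auto": ("one_site", "two_site")}
    if provisional not in kinds:
        raise ValidationError(f"provisional must be one_site|two_site|auto, got {provisional!r}")
    plateau, best_aicc = None, np.inf
    for kind in kinds[provisional]:
        try:
            p, rss, n_params = _provisional_plateau(x, y_raw, kind)
        except Exception:
            continue
        score = aicc(rss, x.size, n_params)
        if np.isfinite(p) and p > 0 and score < best_aicc:
            plateau, best_aicc = p, score
    if plateau is None:
        raise NoSignalError("no titratable signal: provisional fits failed")
    return TitrationCurve(
        concentrations_mM=x,
        deltaA=y_raw / plateau,
        peak_wavelength_nm=float(series.wavelengths_nm[ipeak]),
        anion=series.anion,
        plateau=float(plateau),
    )


def _grid_search_kd(x: np.ndarray, y: np.ndarray, n_grid: int = 10_000) -> float:
    """Brute-force one-site Kd over a log grid (fallback and test oracle)."""
    pos = x[x > 0]
    grid = np.geomspace(pos.min() / 100.0, pos.max() * 100.0, n_grid)
    rss = [np.sum((y - isotherm.one_site(x, kd)) ** 2) for kd in grid]
    return float(grid[int(np.argmin(rss))])


def fit_one_site(curve: TitrationCurve) -> HillFit:
    """Constrained one-site fit dA = x/(Kd + x); sole parameter log(Kd).

    Falls back to a 10^4-point grid search if the local optimizer fails,
    flagging the result instead of raising.
    """
    x, y = curve.concentrations_mM, curve.deltaA
    if np.sum(x > 0) < 3:
        raise ValidationError("need >= 3 distinct positive concentrations")
    model = lmfit.Model(lambda x, log_kd: isotherm.one_site(x, np.exp(log_kd)))
    params = model.make_params(log_kd=np.log(np.median(x[x > 0])))
    flags: tuple[str, ...] = ()
    try:
        out = model.fit(y, params, x=x)
        kd = float(np.exp(out.params["log_kd"].value))
        rss = float(np.sum(out.residual**2))
        err = out.params["log_kd"].stderr
        stderr = {"kd_mM": kd * err if err is not None else np.nan}
        converged = bool(out.success)
    except Exception:
        kd = _grid_search_kd(x, y)
        rss = float(np.sum((y - isotherm.one_site(x, kd)) ** 2))
        stderr = {"kd_mM": np.nan}
        converged = False
        flags = ("grid-search-fallback",)
    return HillFit(
        model_kind="one_site",
        kd_mM=kd,
        rss=rss,
        aicc=aicc(rss, x.size, 1),
        stderr=stderr,
        converged=converged,
        flags=flags,
    )


def fit_two_site(curve: TitrationCurve, n_starts: int = 5) -> HillFit:
    """Constrained two-site fit with amplitudes summing to 1.

    Free parameters: log(Kd1), log(Kd2), Vmax1 in (0, 1).  Multi-start over
    spread initial Kd pairs; the returned fit has Kd1 <= Kd2.  A collapsed
    solution (Kd1 ~ Kd2) is flagged ``reduces-to-one-site``.
    """
    x, y = curve.concentrations_mM, curve.deltaA
    if np.sum(x > 0) < 5:
        raise ValidationError("need >= 5 distinct positive concentrations")
    pos = x[x > 0]

    def f(x, log_kd1, log_kd2, vmax1):
        return isotherm.two_site(x, np.exp(log_kd1), np.exp(log_kd2), vmax1)

    model = lmfit.Model(f)
    lo, hi = np.log(pos.min()), np.log(pos.max())
    # Kd outside ~two decades of the sampled range is unidentifiable from
    # these data; bounding keeps weak-site fits from running away.
    lo_b, hi_b = lo - np.log(100.0), hi + np.log(100.0)
    spreads = np.linspace(0.15, 0.45, n_starts)
    best = None
    for s in spreads:
        params = model.make_params(
            log_kd1=dict(value=lo + (hi - lo) * s, min=lo_b, max=hi_b),
            log_kd2=dict(value=hi - (hi - lo) * s, min=lo_b, max=hi_b),
            vmax1=dict(value=0.5, min=1e-6, max=1.0 - 1e-6),
        )
        try:
            out = model.fit(y, params, x=x)
        except Exception:
            continue
        rss = float(np.sum(out.residual**2))
        if best is None or rss < best[0]:
            best = (rss, out)
    if best is None:
        raise ValidationError("two-site fit failed from every start")
    rss, out = best
    kd1 = float(np.exp(out.params["log_kd1"].value))
    kd2 = float(np.exp(out.params["log_kd2"].value))
    vmax1 = float(out.params["vmax1"].value)
    e1 = out.params["log_kd1"].stderr
    e2 = out.params["log_kd2"].stderr
    ev = out.params["vmax1"].stderr
    if kd1 > kd2:  # identifiability convention
        kd1, kd2 = kd2, kd1
        e1, e2 = e2, e1
        vmax1 = 1.0 - vmax1
    flags: tuple[str, ...] = ()
    if kd2 / kd1 < 1.05:
        flags = ("reduces-to-one-site",)
    return HillFit(
        model_kind="two_site",
        kd1_mM=kd1,
        kd2_mM=kd2,
        vmax1=vmax1,
        rss=rss,
        aicc=aicc(rss, x.size, 3),
        stderr={
            "kd1_mM": kd1 * e1 if e1 is not None else np.nan,
            "kd2_mM": kd2 * e2 if e2 is not None else np.nan,
            "vmax1": ev if ev is not None else np.nan,
        },
        converged=bool(out.success),
        flags=flags,
    )


def select_model(curve: TitrationCurve, delta_aicc: float = 2.0) -> HillFit:
    """Fit both isotherms and keep the better one by small-sample AICc.

    The two-site model must beat the one-site model by more than
    ``delta_aicc`` to be preferred (parsimony on ties).  With fewer than five
    positive concentrations the two-site fit is refused and the one-site
    result is returned with a warning flag.
    """
    one = fit_one_site(curve)
    if np.sum(curve.concentrations_mM > 0) < 5:
        warnings.warn("too few concentrations for a two-site fit; returning one-site", stacklevel=2)
        return HillFit(**{**one.__dict__, "flags": one.flags + ("two-site-refused",)})
    two = fit_two_site(curve)
    if two.aicc < one.aicc - delta_aicc:
        return two
    return one
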