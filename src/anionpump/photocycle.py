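"""Sequential photocycle kinetics and global multi-exponential fitting.

After flash excitation, a microbial rhodopsin relaxes through a chain of
spectrally distinct intermediates (K -> L -> O -> ground for the wild-type
anion pump studied here).  Modeling the chain as irreversible first-order
steps gives closed-form species concentrations (the Bateman solution of
consecutive decays), and the measured difference-absorbance matrix is a sum
of species-associated difference spectra (SADS) weighted by those
concentrations — equivalently, a sum of decay-associated difference spectra
(DADS) weighted by pure exponentials.

``fit_global`` recovers the shared time constants from a wavelength x time
difference-absorbance matrix by variable projection: the time constants are
optimized nonlinearly while the per-wavelength amplitudes, which enter
linearly, are solved exactly by least squares at every step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import expm
from scipy.optimize import least_squares

from .errors import SingularTransformError, ValidationError

__all__ = [
    "TransientDataset",
    "SequentialScheme",
    "GlobalFitResult",
    "OAccumulation",
    "bateman_concentrations",
    "bateman_coefficients",
    "forward_model",
    "dads_from_sads",
    "sads_from_dads",
    "fit_global",
    "assign_intermediates",
    "detect_o_accumulation",
]

# rates closer than this (relatively) use the matrix-exponential path and
# make the DADS<->SADS exponential-basis transform singular
_DEGENERACY_RTOL = 1e-9


@dataclass(frozen=True)
class TransientDataset:
    """Flash-induced difference absorbance on a wavelength x time grid."""

    wavelengths_nm: np.ndarray
    times_s: np.ndarray
    deltaA: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        t = np.asarray(self.times_s, dtype=float)
        dA = np.asarray(self.deltaA, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "deltaA", dA)
        if wl.ndim != 1 or t.ndim != 1:
            raise ValidationError("wavelength and time grids must be 1-D")
        if not np.all(np.diff(wl) > 0):
            raise ValidationError("wavelengths_nm must be strictly ascending")
        if not np.all(np.diff(t) > 0):
            raise ValidationError("times_s must be strictly ascending")
        if np.any(t <= 0):
            raise ValidationError("times_s must be strictly positive")
        if dA.shape != (wl.size, t.size):
            raise ValidationError(
                f"deltaA shape {dA.shape} does not match grids ({wl.size}, {t.size})"
            )
        if not np.all(np.isfinite(dA)):
            raise ValidationError("deltaA contains non-finite cells")

    def select_wavelengths(self, wavelengths_nm: Sequence[float]) -> "TransientDataset":
        """Subset to the rows nearest each requested wavelength (selected-trace mode)."""
        idx = sorted({int(np.argmin(np.abs(self.wavelengths_nm - w))) for w in wavelengths_nm})
        return TransientDataset(self.wavelengths_nm[idx], self.times_s, self.deltaA[idx])


@dataclass(frozen=True)
class SequentialScheme:
    """Ordered chain of first-order decays with one time constant per species."""

    labels: tuple[str, ...]
    tau_s: np.ndarray

    def __init__(self, labels: Sequence[str], tau_s: Sequence[float]):
        tau = np.asarray(tau_s, dtype=float)
        if tau.ndim != 1 or tau.size == 0:
            raise ValidationError("tau_s must be a non-empty 1-D sequence")
        if np.any(tau <= 0):
            raise ValidationError(f"tau_s must be strictly positive, got {tau}")
        if len(labels) != tau.size:
            raise ValidationError(f"{len(labels)} labels for {tau.size} time constants")
        object.__setattr__(self, "labels", tuple(str(l) for l in labels))
        object.__setattr__(self, "tau_s", tau)

    @property
    def n_species(self) -> int:
        return self.tau_s.size

    @property
    def rates(self) -> np.ndarray:
        return 1.0 / self.tau_s


def _is_degenerate(rates: np.ndarray) -> bool:
    k = np.sort(rates)
    return bool(np.any(np.diff(k) <= _DEGENERACY_RTOL * k[1:]))


def bateman_coefficients(tau_s: np.ndarray) -> np.ndarray:
    """Coefficient matrix M of the Bateman solution: c_j(t) = sum_i M[j,i] e^{-k_i t}.

    Lower-triangular with nonzero diagonal for distinct rates, so it also
    serves as the exact linear map between SADS and DADS representations.
    Raises :class:`SingularTransformError` for (near-)coincident rates.
    """
    tau = np.asarray(tau_s, dtype=float)
    k = 1.0 / tau
    n = k.size
    if _is_degenerate(k):
        raise SingularTransformError(
            "coincident time constants: the exponential-basis transform is singular; "
            "use the degenerate (matrix-exponential) concentration path"
        )
    M = np.zeros((n, n))
    for j in range(n):
        prefactor = np.prod(k[:j])  # product of feeding rates, empty -> 1
        for i in range(j + 1):
            denom = np.prod([k[l] - k[i] for l in range(j + 1) if l != i])
            M[j, i] = prefactor / denom
    return M


def _concentrations_expm(rates: np.ndarray, times_s: np.ndarray) -> np.ndarray:
    """Matrix-exponential fallback, exact for repeated rates."""
    n = rates.size
    A = np.diag(-rates)
    for j in range(1, n):
        A[j, j - 1] = rates[j - 1]
    c0 = np.zeros(n)
    c0[0] = 1.0
    out = np.empty((n, times_s.size))
    for i, t in enumerate(times_s):
        out[:, i] = expm(A * t) @ c0
    return out


def bateman_concentrations(scheme: SequentialScheme, times_s) -> np.ndarray:
    """Species concentrations of the irreversible chain, shape (n_species, n_times).

    The first species starts at unit concentration (photoexcitation treated
    as instantaneous); each subsequent species is fed by its predecessor.
    Values are clipped of sub-1e-12 negative round-off so they lie in [0, 1].
    """
    t = np.atleast_1d(np.asarray(times_s, dtype=float))
    if np.any(t < 0):
        raise ValidationError("times_s must be >= 0")
    k = scheme.rates
    if _is_degenerate(k):
        conc = _concentrations_expm(k, t)
    else:
        M = bateman_coefficients(scheme.tau_s)
        E = np.exp(-np.outer(k, t))  # (n_species exponentials, n_times)
        conc = M @ E
    return np.clip(conc, 0.0, 1.0)


def forward_model(
    scheme: SequentialScheme, sads: np.ndarray, wavelengths_nm, times_s
) -> TransientDataset:
    """Noise-free difference-absorbance matrix dA(lambda, t) = sum_j SADS_j(lambda) c_j(t)."""
    wl = np.asarray(wavelengths_nm, dtype=float)
    sads = np.asarray(sads, dtype=float)
    if sads.shape != (wl.size, scheme.n_species):
        raise ValidationError(
            f"sads shape {sads.shape} does not match ({wl.size} wavelengths, "
            f"{scheme.n_species} species)"
        )
    conc = bateman_concentrations(scheme, times_s)
    return TransientDataset(wl, np.asarray(times_s, dtype=float), sads @ conc)


def dads_from_sads(scheme: SequentialScheme, sads: np.ndarray) -> np.ndarray:
    """Map species-associated to decay-associated difference spectra.

    Expanding the Bateman concentrations in the exponential basis
    {e^{-t/tau_i}} gives dA = DADS @ E with DADS = SADS @ M.
    """
    sads = np.asarray(sads, dtype=float)
    if sads.shape[1] != scheme.n_species:
        raise ValidationError("sads column count must equal the species count")
    return sads @ bateman_coefficients(scheme.tau_s)


def sads_from_dads(scheme: SequentialScheme, dads: np.ndarray) -> np.ndarray:
    """Inverse map of :func:`dads_from_sads` (exact; M is triangular)."""
    dads = np.asarray(dads, dtype=float)
    if dads.shape[1] != scheme.n_species:
        raise ValidationError("dads column count must equal the species count")
    M = bateman_coefficients(scheme.tau_s)
    return np.linalg.solve(M.T, dads.T).T


@dataclass(frozen=True)
class GlobalFitResult:
    """Outcome of a global multi-exponential fit of one transient matrix."""

    scheme: SequentialScheme
    dads: np.ndarray
    sads: np.ndarray | None
    rss: float
    per_tau_stderr: np.ndarray
    converged: bool
    degenerate: bool = False
    n_starts: int = 0
    wavelengths_nm: np.ndarray = field(default_factory=lambda: np.empty(0))

    def reconstruction(self, times_s) -> np.ndarray:
        """Model matrix on an arbitrary time grid from the DADS representation."""
        t = np.asarray(times_s, dtype=float)
        E = np.exp(-np.outer(self.scheme.rates, t))
        return self.dads @ E


def _dads_solve(E: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact amplitudes for fixed taus: Y (n_wl, n_t) ~ D @ E with E (n_exp, n_t)."""
    coef, *_ = np.linalg.lstsq(E.T, Y.T, rcond=None)
    resid = Y - coef.T @ E
    return coef.T, resid


def _residual_factory(times_s: np.ndarray, Y: np.ndarray):
    def residual(log_tau: np.ndarray) -> np.ndarray:
        E = np.exp(-np.outer(np.exp(-log_tau), times_s) * 1.0)
        # log_tau stores log(tau); rate = exp(-log_tau)
        _, resid = _dads_solve(E, Y)
        return resid.ravel()

    return residual


def _multistart_inits(times_s: np.ndarray, n_exp: int, n_starts: int) -> list[np.ndarray]:
    t_min, t_max = times_s[0], times_s[-1]
    centers = np.geomspace(t_min, t_max, n_exp + 2)[1:-1]
    offsets = np.linspace(-0.9, 0.9, n_starts)
    return [centers * 10.0**off for off in offsets]


def fit_global(
    data: TransientDataset,
    n_exp: int,
    init_tau_s: Sequence[float] | None = None,
    n_starts: int = 8,
    wavelengths_nm: Sequence[float] | None = None,
) -> GlobalFitResult:
    """Globally fit ``n_exp`` shared time constants to a transient matrix.

    Taus are optimized in log space (positivity by construction) from a
    multi-start log grid spanning the observed time range; per-wavelength
    amplitudes are projected out exactly at each step.  The best start by
    residual sum of squares wins; ties go to the lexicographically smallest
    tau vector.  Never raises on non-convergence — the best candidate is
    returned with ``converged=False``.

    Parameters
    ----------
    data : TransientDataset
        Full matrix, or pass ``wavelengths_nm`` to fit selected traces only
        (e.g. 470/570/600 nm as in single-wavelength kinetic analysis).
    n_exp : int
        Number of exponentials (sequential species) to fit.
    init_tau_s : sequence of float, optional
        Extra user-supplied starting tau vector, tried alongside the grid.
    """
    if n_exp < 1:
        raise ValidationError(f"n_exp must be >= 1, got {n_exp}")
    if data.times_s.size < 2 * n_exp:
        raise ValidationError(
            f"need at least {2 * n_exp} time points for n_exp={n_exp}, "
            f"got {data.times_s.size}"
        )
    if wavelengths_nm is not None:
        data = data.select_wavelengths(wavelengths_nm)
    t, Y = data.times_s, data.deltaA

    residual = _residual_factory(t, Y)
    starts = _multistart_inits(t, n_exp, n_starts)
    if init_tau_s is not None:
        init = np.asarray(init_tau_s, dtype=float)
        if init.size != n_exp or np.any(init <= 0):
            raise ValidationError("init_tau_s must hold n_exp positive values")
        starts.insert(0, init)

    best = None
    any_success = False
    for tau0 in starts:
        sol = least_squares(residual, np.log(np.asarray(tau0, dtype=float)), method="lm")
        rss = 2.0 * sol.cost
        tau_sorted = np.sort(np.exp(sol.x))
        key = (rss, tuple(tau_sorted))
        if best is None or key < best[0]:
            best = (key, sol, tau_sorted)
        any_success = any_success or bool(sol.success)

    (_, sol, tau) = best
    rss = 2.0 * sol.cost
    rates = 1.0 / tau
    E = np.exp(-np.outer(rates, t))
    dads, resid = _dads_solve(E, Y)

    degenerate = bool(np.any(tau[1:] / tau[:-1] < 1.05)) if n_exp > 1 else False
    if degenerate:
        warnings.warn(
            f"fitted time constants nearly coincident: {tau}; "
            "the model order may be too high for these data",
            stacklevel=2,
        )

    scheme = SequentialScheme([str(i + 1) for i in range(n_exp)], tau)
    try:
        sads = sads_from_dads(scheme, dads)
    except SingularTransformError:
        sads = None

    # Gauss-Newton stderr of log(tau) from the varpro Jacobian at the optimum,
    # scaled by the residual variance (amplitudes count as parameters too).
    dof = Y.size - n_exp - n_exp * Y.shape[0]
    per_tau_stderr = np.full(n_exp, np.nan)
    if dof > 0 and rss > 0:
        J = sol.jac
        try:
            cov = np.linalg.inv(J.T @ J) * (rss / dof)
            # sol.x is log(tau) in fit order; map to sorted order
            order = np.argsort(np.exp(sol.x))
            per_tau_stderr = tau * np.sqrt(np.diag(cov))[order]
        except np.linalg.LinAlgError:
            pass

    return GlobalFitResult(
        scheme=scheme,
        dads=dads,
        sads=sads,
        rss=float(rss),
        per_tau_stderr=per_tau_stderr,
        converged=any_success,
        degenerate=degenerate,
        n_starts=len(starts),
        wavelengths_nm=data.wavelengths_nm,
    )


# ---------------------------------------------------------------------------
# Intermediate assignment and O-intermediate accumulation
# ---------------------------------------------------------------------------

_L_WINDOW = (440.0, 500.0)
_O_WINDOW = (590.0, 640.0)
_BLEACH_WINDOW = (520.0, 590.0)
_RED_SHIFT_MIN_NM = 520.0


def _positive_peak(wl: np.ndarray, spectrum: np.ndarray, floor: float):
    """(wavelength, height) of the positive maximum, or None below the floor.

    The floor combines a fraction of the global amplitude with a robust
    noise estimate from the spectrum's first differences, so a fitted
    bleach-only species whose only positive excursions are noise is not
    awarded a band.
    """
    if spectrum.size >= 10:  # differences reflect noise only on a dense grid
        sigma = np.median(np.abs(np.diff(spectrum))) / (0.6745 * np.sqrt(2.0))
        floor = max(floor, 5.0 * sigma)
    i = int(np.argmax(spectrum))
    if spectrum[i] <= floor:
        return None
    return wl[i], spectrum[i]


def assign_intermediates(result: GlobalFitResult) -> SequentialScheme:
    """Label fitted species by their SADS band positions.

    A positive maximum in 440-500 nm marks an L-like (blue-shifted)
    intermediate, in 590-640 nm an O-like (red-shifted) one; the earliest,
    fastest species with a red-shifted positive band is K-like.  A species
    with no positive lobe is labeled ``bleach-only``.  Labels are never
    duplicated: a second candidate for a taken label keeps a numbered
    fallback name.
    """
    if result.sads is None:
        raise ValidationError("no SADS available (degenerate fit); cannot assign")
    wl = result.wavelengths_nm
    sads = result.sads
    n = sads.shape[1]
    floor = 1e-3 * np.max(np.abs(sads)) if np.any(sads) else 0.0

    labels: list[str | None] = [None] * n
    taken: set[str] = set()

    def claim(j: int, label: str) -> None:
        if label in taken:
            label = f"{label}{j + 1}"
        labels[j] = label
        taken.add(label)

    peaks = [_positive_peak(wl, sads[:, j], floor) for j in range(n)]
    for j, peak in enumerate(peaks):
        if peak is None:
            claim(j, "bleach-only")
            continue
        lam, _ = peak
        if _L_WINDOW[0] <= lam <= _L_WINDOW[1]:
            claim(j, "L")
        elif _O_WINDOW[0] <= lam <= _O_WINDOW[1]:
            claim(j, "O")
    # K: fastest unlabeled species whose positive band is red-shifted
    candidates = [
        j
        for j in range(n)
        if labels[j] is None and peaks[j] is not None and peaks[j][0] >= _RED_SHIFT_MIN_NM
    ]
    if candidates and "K" not in taken:
        claim(min(candidates, key=lambda j: result.scheme.tau_s[j]), "K")
    for j in range(n):
        if labels[j] is None:
            claim(j, f"species{j + 1}")
    return SequentialScheme(labels, result.scheme.tau_s)


@dataclass(frozen=True)
class OAccumulation:
    """Decision and evidence for O-intermediate accumulation."""

    accumulating: bool
    score: float
    threshold: float
    warning: str | None = None


def detect_o_accumulation(result: GlobalFitResult, threshold: float = 0.10) -> OAccumulation:
    """Decide whether the photocycle accumulates an O intermediate.

    The score is the largest positive SADS amplitude in the O band
    (590-640 nm, any species) relative to the deepest ground-state bleach
    (520-590 nm).  Mutants that skip the O state score near zero; the
    wild-type scores about half the bleach depth.
    """
    if result.sads is None:
        raise ValidationError("no SADS available (degenerate fit); cannot score")
    wl = result.wavelengths_nm
    in_o = (wl >= _O_WINDOW[0]) & (wl <= _O_WINDOW[1])
    in_bleach = (wl >= _BLEACH_WINDOW[0]) & (wl <= _BLEACH_WINDOW[1])
    if not np.any(in_o) or not np.any(in_bleach):
        raise ValidationError("wavelength grid does not cover the O/bleach windows")
    numerator = max(float(np.max(result.sads[in_o, :])), 0.0)
    depth = -float(np.min(result.sads[in_bleach, :]))
    if depth <= 0:
        return OAccumulation(
            accumulating=False,
            score=float("nan"),
            threshold=threshold,
            warning="no ground-state bleach: O-accumulation score undefined",
        )
    score = numerator / depth
    return OAccumulation(accumulating=bool(score >= threshold), score=score, threshold=threshold)
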