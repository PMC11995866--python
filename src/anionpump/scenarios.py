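"""Ground-truth scenarios for the synthetic-data generators.

A scenario bundles every parameter a generator needs — spectral bands,
dissociation constants, photocycle time constants, slopes, noise levels and
the RNG seed — so that each synthetic dataset has a fully known ground truth
against which parameter recovery can be measured.

A small catalog of named scenarios is shipped as YAML files
(``anionpump/data/scenarios``).  Their kinetic and binding parameters are the
values reported for the wild-type pump and its Arg71/His167 mutants; band
positions are approximate (the source spectra are published as figures, not
tables) and are documented as package choices in the methods note.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .bands import DifferenceBand, SpectralBandModel
from .errors import ValidationError

__all__ = [
    "TitrationScenario",
    "PhotocycleScenario",
    "TransportScenario",
    "PanelScenario",
    "load_scenario",
    "scenario_catalog",
    "log_spaced",
]


def log_spaced(start: float, stop: float, num: int) -> np.ndarray:
    """Logarithmically spaced grid, endpoints included."""
    if start <= 0 or stop <= start or num < 2:
        raise ValidationError("log grid needs 0 < start < stop and num >= 2")
    return np.geomspace(start, stop, num)


def _as_array(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


def _check_ascending(name: str, values: np.ndarray, strictly: bool = True) -> None:
    d = np.diff(values)
    if strictly and not np.all(d > 0):
        raise ValidationError(f"{name} must be strictly ascending")
    if not strictly and not np.all(d >= 0):
        raise ValidationError(f"{name} must be ascending")


@dataclass(frozen=True)
class TitrationScenario:
    """Anion-titration series with a one- or two-site binding ground truth.

    The spectrum at concentration ``c`` is the isotherm-weighted mixture of
    the unbound and anion-bound bands; ``shift_direction`` records whether
    binding blue- or red-shifts the absorption maximum (chloride and sulfate
    respectively, for the wild-type pump).
    """

    name: str
    model_kind: str  # "one_site" | "two_site"
    unbound_band: SpectralBandModel
    bound_band: SpectralBandModel
    shift_direction: str  # "blue" | "red"
    concentrations_mM: np.ndarray
    kd_mM: float | None = None
    kd1_mM: float | None = None
    kd2_mM: float | None = None
    vmax1: float | None = None
    wavelengths_nm: np.ndarray = field(
        default_factory=lambda: np.arange(350.0, 751.0, 1.0)
    )
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "concentrations_mM", _as_array(self.concentrations_mM))
        object.__setattr__(self, "wavelengths_nm", _as_array(self.wavelengths_nm))
        if self.model_kind not in ("one_site", "two_site"):
            raise ValidationError(f"model_kind must be one_site|two_site, got {self.model_kind!r}")
        if self.shift_direction not in ("blue", "red"):
            raise ValidationError(f"shift_direction must be blue|red, got {self.shift_direction!r}")
        if self.model_kind == "one_site":
            if self.kd_mM is None or self.kd_mM <= 0:
                raise ValidationError(f"kd_mM must be > 0, got {self.kd_mM}")
        else:
            for fname in ("kd1_mM", "kd2_mM"):
                v = getattr(self, fname)
                if v is None or v <= 0:
                    raise ValidationError(f"{fname} must be > 0, got {v}")
            if self.vmax1 is None or not 0.0 < self.vmax1 < 1.0:
                raise ValidationError(f"vmax1 must be in (0, 1), got {self.vmax1}")
        if np.any(self.concentrations_mM < 0):
            raise ValidationError("concentrations_mM must be >= 0")
        _check_ascending("concentrations_mM", self.concentrations_mM)
        _check_ascending("wavelengths_nm", self.wavelengths_nm)
        if self.noise_sigma < 0:
            raise ValidationError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        # a blue shift means the bound band sits at shorter wavelength
        d = self.bound_band.lambda_max_nm - self.unbound_band.lambda_max_nm
        if self.shift_direction == "blue" and d >= 0:
            raise ValidationError("shift_direction=blue but bound_band is not blue of unbound_band")
        if self.shift_direction == "red" and d <= 0:
            raise ValidationError("shift_direction=red but bound_band is not red of unbound_band")

    def fraction_bound(self, concentrations_mM=None) -> np.ndarray:
        """Isotherm value f(c) in [0, 1] at each concentration."""
        from . import isotherm

        c = self.concentrations_mM if concentrations_mM is None else _as_array(concentrations_mM)
        if self.model_kind == "one_site":
            return isotherm.one_site(c, self.kd_mM)
        return isotherm.two_site(c, self.kd1_mM, self.kd2_mM, self.vmax1)

    def with_seed(self, seed: int) -> "TitrationScenario":
        return dataclasses.replace(self, seed=int(seed))


@dataclass(frozen=True)
class PhotocycleScenario:
    """Irreversible sequential photocycle with known taus and species spectra.

    ``tau_s`` are the decay time constants of the chain (first species present
    at unit concentration at t=0); ``sads`` give each species' difference
    spectrum as a positive intermediate band minus a ground-state bleach band.
    An O-free mutant is emulated by a final species whose positive-band
    amplitude is zero (bleach-only recovery phase).
    """

    name: str
    tau_s: Sequence[float]
    sads: Sequence[DifferenceBand]
    labels: Sequence[str] | None = None
    wavelengths_nm: np.ndarray = field(
        default_factory=lambda: np.arange(420.0, 711.0, 10.0)
    )
    times_s: np.ndarray = field(default_factory=lambda: log_spaced(1e-5, 4.0, 60))
    noise_sigma: float = 0.0
    noise_relative: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "tau_s", tuple(float(t) for t in self.tau_s))
        object.__setattr__(self, "sads", tuple(self.sads))
        object.__setattr__(self, "wavelengths_nm", _as_array(self.wavelengths_nm))
        object.__setattr__(self, "times_s", _as_array(self.times_s))
        if any(t <= 0 for t in self.tau_s):
            raise ValidationError("tau_s must all be > 0")
        if len(self.sads) != len(self.tau_s):
            raise ValidationError(
                f"sads has {len(self.sads)} entries for {len(self.tau_s)} time constants"
            )
        if self.labels is not None and len(self.labels) != len(self.tau_s):
            raise ValidationError("labels length must match tau_s")
        if np.any(self.times_s <= 0):
            raise ValidationError("times_s must be strictly positive")
        _check_ascending("times_s", self.times_s)
        _check_ascending("wavelengths_nm", self.wavelengths_nm)
        if self.noise_sigma < 0:
            raise ValidationError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        if self.noise_relative is not None and self.noise_relative < 0:
            raise ValidationError("noise_relative must be >= 0")

    def sads_matrix(self) -> np.ndarray:
        """SADS evaluated on the wavelength grid, shape (n_wavelengths, n_species)."""
        return np.column_stack([band(self.wavelengths_nm) for band in self.sads])

    def with_seed(self, seed: int) -> "PhotocycleScenario":
        return dataclasses.replace(self, seed=int(seed))


@dataclass(frozen=True)
class TransportScenario:
    """Light-induced pH trace: linear baseline drift plus an illumination ramp."""

    name: str
    true_slope: float  # pH/s during illumination (alkalization positive)
    drift_slope: float
    light_on_s: float
    light_off_s: float
    duration_s: float
    sample_interval_s: float = 1.0
    noise_sigma: float = 0.0
    baseline_ph: float = 7.0
    relax_tau_s: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValidationError(f"duration_s must be > 0, got {self.duration_s}")
        if not 0 <= self.light_on_s < self.light_off_s <= self.duration_s:
            raise ValidationError(
                "require 0 <= light_on_s < light_off_s <= duration_s, got "
                f"({self.light_on_s}, {self.light_off_s}, {self.duration_s})"
            )
        if self.sample_interval_s <= 0:
            raise ValidationError(f"sample_interval_s must be > 0, got {self.sample_interval_s}")
        if self.noise_sigma < 0:
            raise ValidationError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        if self.relax_tau_s <= 0:
            raise ValidationError(f"relax_tau_s must be > 0, got {self.relax_tau_s}")

    def with_seed(self, seed: int) -> "TransportScenario":
        return dataclasses.replace(self, seed=int(seed))


@dataclass(frozen=True)
class PanelScenario:
    """Mutant panel with planted transport activities and expression levels.

    ``true_activity_cl`` / ``true_activity_so4`` are per-mutant initial-slope
    ground truths (pH/s); ``expression`` is the relative amount of expressed
    protein (WT = 1) used downstream for normalization; replicates are drawn
    with fractional noise ``replicate_cv``.
    """

    name: str
    mutant_names: Sequence[str]
    true_activity_cl: Sequence[float]
    true_activity_so4: Sequence[float]
    expression: Sequence[float]
    n_replicates: int = 4
    replicate_cv: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        names = tuple(self.mutant_names)
        object.__setattr__(self, "mutant_names", names)
        object.__setattr__(self, "true_activity_cl", _as_array(self.true_activity_cl))
        object.__setattr__(self, "true_activity_so4", _as_array(self.true_activity_so4))
        object.__setattr__(self, "expression", _as_array(self.expression))
        n = len(names)
        for fname in ("true_activity_cl", "true_activity_so4", "expression"):
            if len(getattr(self, fname)) != n:
                raise ValidationError(f"{fname} length must match mutant_names ({n})")
        if "WT" not in names:
            raise ValidationError("mutant_names must include 'WT'")
        if len(set(names)) != n:
            raise ValidationError("mutant_names must be unique")
        if np.any(self.expression <= 0):
            raise ValidationError("expression must be > 0 for every mutant")
        if self.n_replicates < 3:
            raise ValidationError(f"n_replicates must be >= 3, got {self.n_replicates}")
        if self.replicate_cv < 0:
            raise ValidationError(f"replicate_cv must be >= 0, got {self.replicate_cv}")

    def with_seed(self, seed: int) -> "PanelScenario":
        return dataclasses.replace(self, seed=int(seed))


# ---------------------------------------------------------------------------
# YAML catalog
# ---------------------------------------------------------------------------

_BAND_KEYS = {"lambda_max_nm", "sigma_nm", "amplitude"}


def _band_from_dict(d: dict, where: str) -> SpectralBandModel:
    unknown = set(d) - _BAND_KEYS
    if unknown:
        raise ValidationError(f"unknown keys {sorted(unknown)} in {where}")
    return SpectralBandModel(**d)


def _grid_from_spec(spec, kind: str) -> np.ndarray:
    """Expand a grid spec: explicit list, linear range or log range."""
    if isinstance(spec, (list, tuple, np.ndarray)):
        return _as_array(spec)
    if not isinstance(spec, dict):
        raise ValidationError(f"bad grid spec for {kind}: {spec!r}")
    keys = set(spec)
    if keys == {"start", "stop", "step"}:
        return np.arange(spec["start"], spec["stop"] + 0.5 * spec["step"], spec["step"])
    if keys in ({"log_start", "log_stop", "num"}, {"log_start", "log_stop", "num", "include_zero"}):
        grid = log_spaced(spec["log_start"], spec["log_stop"], int(spec["num"]))
        if spec.get("include_zero"):
            grid = np.concatenate([[0.0], grid])
        return grid
    raise ValidationError(f"unknown grid keys {sorted(keys)} for {kind}")


_SCENARIO_FIELDS = {
    "titration": {f.name for f in dataclasses.fields(TitrationScenario)},
    "photocycle": {f.name for f in dataclasses.fields(PhotocycleScenario)},
    "transport": {f.name for f in dataclasses.fields(TransportScenario)},
    "panel": {f.name for f in dataclasses.fields(PanelScenario)},
}


def scenario_from_dict(cfg: dict):
    """Build a scenario object from a parsed config mapping.

    Unknown keys are rejected rather than ignored so that typos in config
    files fail loudly.
    """
    cfg = dict(cfg)
    kind = cfg.pop("kind", None)
    if kind not in _SCENARIO_FIELDS:
        raise ValidationError(f"scenario kind must be one of {sorted(_SCENARIO_FIELDS)}, got {kind!r}")
    unknown = set(cfg) - _SCENARIO_FIELDS[kind]
    if unknown:
        raise ValidationError(f"unknown scenario keys {sorted(unknown)} for kind {kind!r}")
    if kind == "titration":
        cfg["unbound_band"] = _band_from_dict(cfg["unbound_band"], "unbound_band")
        cfg["bound_band"] = _band_from_dict(cfg["bound_band"], "bound_band")
        cfg["concentrations_mM"] = _grid_from_spec(cfg["concentrations_mM"], "concentrations_mM")
        if "wavelengths_nm" in cfg:
            cfg["wavelengths_nm"] = _grid_from_spec(cfg["wavelengths_nm"], "wavelengths_nm")
        return TitrationScenario(**cfg)
    if kind == "photocycle":
        sads = []
        for i, entry in enumerate(cfg["sads"]):
            unknown = set(entry) - {"positive", "bleach"}
            if unknown:
                raise ValidationError(f"unknown keys {sorted(unknown)} in sads[{i}]")
            sads.append(
                DifferenceBand(
                    positive=_band_from_dict(entry["positive"], f"sads[{i}].positive"),
                    bleach=_band_from_dict(entry["bleach"], f"sads[{i}].bleach"),
                )
            )
        cfg["sads"] = sads
        if "wavelengths_nm" in cfg:
            cfg["wavelengths_nm"] = _grid_from_spec(cfg["wavelengths_nm"], "wavelengths_nm")
        if "times_s" in cfg:
            cfg["times_s"] = _grid_from_spec(cfg["times_s"], "times_s")
        return PhotocycleScenario(**cfg)
    if kind == "transport":
        return TransportScenario(**cfg)
    return PanelScenario(**cfg)


def _catalog_dir():
    return resources.files("anionpump") / "data" / "scenarios"


def scenario_catalog() -> list[str]:
    """Names of the scenarios shipped with the package."""
    return sorted(p.name.removesuffix(".yaml") for p in _catalog_dir().iterdir() if p.name.endswith(".yaml"))


def load_scenario(name_or_path: str | Path, seed: int | None = None):
    """Load a scenario by catalog name or from a YAML file path."""
    path = Path(name_or_path)
    if path.suffix in (".yaml", ".yml") and path.exists():
        text = path.read_text()
    else:
        candidate = _catalog_dir() / f"{name_or_path}.yaml"
        try:
            text = candidate.read_text()
        except (FileNotFoundError, OSError) as exc:
            raise ValidationError(
                f"no scenario file {name_or_path!r}; catalog: {scenario_catalog()}"
            ) from exc
    cfg = yaml.safe_load(text)
    scenario = scenario_from_dict(cfg)
    if seed is not None:
        scenario = scenario.with_seed(seed)
    return scenario
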