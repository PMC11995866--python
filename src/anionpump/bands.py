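"""Gaussian spectral bands in wavelength space.

Visible absorption bands of retinal proteins are modeled as Gaussians in
wavelength (nm).  This is a deliberate simplification: real retinylidene
bands are closer to Gaussian in energy and carry vibronic shoulders, but a
wavelength-space Gaussian reproduces band positions and anion-induced shifts,
which is all the downstream titration and photocycle analysis consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

__all__ = ["SpectralBandModel", "DifferenceBand"]


@dataclass(frozen=True)
class SpectralBandModel:
    """A single Gaussian absorption band.

    Parameters
    ----------
    lambda_max_nm : float
        Band maximum in nm; constrained to the 300-800 nm visible/near-UV
        window of retinal protein spectroscopy.
    sigma_nm : float
        Gaussian standard deviation in nm (must be positive).
    amplitude : float
        Peak absorbance, dimensionless (must be nonnegative).
    """

    lambda_max_nm: float
    sigma_nm: float
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if not 300.0 <= self.lambda_max_nm <= 800.0:
            raise ValidationError(
                f"lambda_max_nm={self.lambda_max_nm} outside [300, 800] nm"
            )
        if not self.sigma_nm > 0:
            raise ValidationError(f"sigma_nm must be > 0, got {self.sigma_nm}")
        if self.amplitude < 0:
            raise ValidationError(f"amplitude must be >= 0, got {self.amplitude}")

    def __call__(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        wl = np.asarray(wavelengths_nm, dtype=float)
        z = (wl - self.lambda_max_nm) / self.sigma_nm
        return self.amplitude * np.exp(-0.5 * z * z)


@dataclass(frozen=True)
class DifferenceBand:
    """Difference spectrum of one photointermediate: positive band minus bleach.

    The species-associated difference spectrum (SADS) of an intermediate is
    its own absorption band minus the depleted ground-state band.  Amplitudes
    are independent so partial bleach contributions can be expressed.
    """

    positive: SpectralBandModel
    bleach: SpectralBandModel

    def __call__(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        return self.positive(wavelengths_nm) - self.bleach(wavelengths_nm)
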