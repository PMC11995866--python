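"""Hyperbolic (Hill exponent 1) binding isotherms.

One-site:   dA(x) = Vmax * x / (Kd + x)
Two-site:   dA(x) = Vmax1 * x / (Kd1 + x) + Vmax2 * x / (Kd2 + x)

with the total amplitude fixed at 1 in the constrained fits (Vmax = 1,
Vmax1 + Vmax2 = 1).  Concentrations x and dissociation constants Kd are in mM.
"""

from __future__ import annotations

import numpy as np

__all__ = ["one_site", "two_site"]


def one_site(x, kd_mM: float, vmax: float = 1.0):
    """Fractional saturation of a single site at concentration ``x`` (mM)."""
    x = np.asarray(x, dtype=float)
    return vmax * x / (kd_mM + x)


def two_site(x, kd1_mM: float, kd2_mM: float, vmax1: float, vmax_total: float = 1.0):
    """Sum of two independent hyperbolic sites; amplitudes sum to ``vmax_total``."""
    x = np.asarray(x, dtype=float)
    vmax2 = vmax_total - vmax1
    return vmax1 * x / (kd1_mM + x) + vmax2 * x / (kd2_mM + x)
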