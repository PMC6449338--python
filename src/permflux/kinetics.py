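"""Spherical-cell conversion of first-order uptake kinetics to permeability.

Experimental uptake of a permeant into cells or liposomes is commonly
reported as a single-step first-order process with rate constant k.  For
a spherical cell of radius r the membrane permeability follows from the
surface-to-volume ratio as P = k r / 3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .membrane1d import UptakeSeries

#: 1 pL in m^3
PICOLITER_TO_M3 = 1.0e-15


class KineticsFitError(RuntimeError):
    pass


@dataclass(frozen=True)
class FirstOrderFit:
    """Fitted uptake kinetics: rate k (1/s), plateau, residual RMS."""

    k: float
    plateau: float
    residual_rms: float
    offset: float = 0.0


@dataclass(frozen=True)
class CellGeometry:
    """Spherical cell defined by its volume in m^3."""

    volume: float

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError("volume must be positive")

    @classmethod
    def from_picoliters(cls, volume_pl: float) -> "CellGeometry":
        return cls(volume=volume_pl * PICOLITER_TO_M3)

    @property
    def radius(self) -> float:
        """Radius in m: r = (3 V / 4 pi)^(1/3)."""
        return radius_from_volume(self.volume)


def radius_from_volume(volume: float) -> float:
    """Exact sphere inversion, volume in m^3 -> radius in m."""
    if volume <= 0:
        raise ValueError("volume must be positive")
    return (3.0 * volume / (4.0 * math.pi)) ** (1.0 / 3.0)


def fit_first_order(uptake: UptakeSeries, free_offset: bool = False) -> FirstOrderFit:
    """Unweighted least-squares fit of C(t) = C_inf (1 - exp(-k t)).

    With ``free_offset`` an additive baseline C0 is also fitted.
    Initial guesses: C_inf = max value, k from the initial slope.
    """
    t = uptake.times
    y = uptake.values
    if np.allclose(y, y[0]):
        raise KineticsFitError("uptake values are all equal; nothing to fit")
    c_inf0 = float(np.max(y))
    slope0 = (y[1] - y[0]) / (t[1] - t[0])
    k0 = abs(slope0) / c_inf0 if c_inf0 > 0 and slope0 > 0 else 1.0 / float(t[-1])
    try:
        if free_offset:
            popt, _ = curve_fit(
                lambda tt, c, k, c0: c0 + c * (1.0 - np.exp(-k * tt)),
                t, y, p0=(c_inf0, k0, 0.0), maxfev=20_000,
            )
            c_inf, k, c0 = popt
            resid = y - (c0 + c_inf * (1.0 - np.exp(-k * t)))
        else:
            popt, _ = curve_fit(
                lambda tt, c, k: c * (1.0 - np.exp(-k * tt)),
                t, y, p0=(c_inf0, k0), maxfev=20_000,
            )
            c_inf, k = popt
            c0 = 0.0
            resid = y - c_inf * (1.0 - np.exp(-k * t))
    except (RuntimeError, ValueError) as exc:
        raise KineticsFitError(f"first-order uptake fit failed: {exc}") from exc
    if k <= 0:
        raise KineticsFitError(f"fitted rate constant is non-positive ({k:.3g})")
    return FirstOrderFit(k=float(k), plateau=float(c_inf),
                         residual_rms=float(np.sqrt(np.mean(resid**2))),
                         offset=float(c0))


def permeability_from_kinetics(k: float, radius: float) -> float:
    """P = k r / 3 (k in 1/s, r in m, P in m/s)."""
    if k <= 0 or radius <= 0:
        raise ValueError("k and radius must be positive")
    return k * radius / 3.0


def kinetic_constant(P: float, radius: float) -> float:
    """Inverse of the spherical-cell relation: k = 3 P / r."""
    if P <= 0 or radius <= 0:
        raise ValueError("P and radius must be positive")
    return 3.0 * P / radius
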