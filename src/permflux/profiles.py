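"""Structural bilayer observables from particle coordinate frames.

Number-density profiles along the membrane normal, head-group peak
positions (the per-leaflet membrane half-thickness) with their linear
regression against cholesterol content, and acyl-chain order parameters
S = <3 cos^2 theta - 1> / 2 per chain carbon.

Frames are plain tables (pandas DataFrame with columns ``frame``,
``species``, ``leaflet``, ``z``); a Gaussian-mixture fixture generator
is provided so every operation is testable without MD trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

FRAME_COLUMNS = ("frame", "species", "leaflet", "z")


@dataclass(frozen=True)
class DensityProfile:
    """Number density (nm^-3) of one species on a uniform z grid."""

    z: np.ndarray
    density: np.ndarray
    bin_width: float
    area: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "z", np.asarray(self.z, dtype=float))
        object.__setattr__(self, "density", np.asarray(self.density, dtype=float))
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")


@dataclass(frozen=True)
class OrderParameterProfile:
    """Order parameter per chain carbon, bounded in [-0.5, 1]."""

    carbons: np.ndarray
    S: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "carbons", np.asarray(self.carbons, dtype=int))
        object.__setattr__(self, "S", np.asarray(self.S, dtype=float))
        if np.any(self.S < -0.5 - 1e-12) or np.any(self.S > 1.0 + 1e-12):
            raise ValueError("order parameters must lie in [-0.5, 1]")


@dataclass(frozen=True)
class ThicknessPoint:
    """Cholesterol content (mol%) versus per-leaflet head-group |z_peak|."""

    cholesterol_percent: float
    z_peak: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.cholesterol_percent <= 100.0:
            raise ValueError("cholesterol mol% must be in [0, 100]")


# --------------------------------------------------------------------------


def density_profile(frames: pd.DataFrame, species: str, area: float,
                    bin_width: float = 0.05,
                    z_range: tuple | None = None) -> DensityProfile:
    """Frame-averaged number density of one species along z.

    The count histogram is averaged over frames and divided by the bin
    volume ``bin_width * area`` (nm^3).
    """
    if area <= 0:
        raise ValueError("area must be positive")
    known = set(frames["species"].unique())
    if species not in known:
        raise ValueError(f"unknown species {species!r}; frames contain {sorted(known)}")
    sel = frames[frames["species"] == species]
    n_frames = int(frames["frame"].nunique())
    zvals = sel["z"].to_numpy(dtype=float)
    if z_range is None:
        lo, hi = zvals.min(), zvals.max()
        pad = bin_width
        z_range = (lo - pad, hi + pad)
    n_bins = max(1, int(np.ceil((z_range[1] - z_range[0]) / bin_width)))
    edges = z_range[0] + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(zvals, bins=edges)
    density = counts / n_frames / (bin_width * area)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return DensityProfile(z=centers, density=density, bin_width=bin_width, area=area)


def headgroup_peak(profile: DensityProfile, leaflet) -> float:
    """|z| of the density maximum on one side of the membrane.

    ``leaflet`` is "outer"/+1 (z > 0) or "inner"/-1 (z < 0).  The peak
    position is refined by a 3-point parabolic fit around the top bin.
    """
    sign = {"outer": 1, "inner": -1, 1: 1, -1: -1}.get(leaflet)
    if sign is None:
        raise ValueError("leaflet must be 'outer'/'inner' or +1/-1")
    mask = profile.z > 0 if sign > 0 else profile.z < 0
    if mask.sum() < 3:
        raise ValueError("too few bins on the requested side")
    z = profile.z[mask]
    y = profile.density[mask]
    i = int(np.argmax(y))
    if i == 0 or i == y.size - 1:
        raise ValueError("density is monotone on this side; no interior peak")
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    shift = 0.0 if denom == 0 else 0.5 * (y[i - 1] - y[i + 1]) / denom
    dz = z[1] - z[0]
    return float(abs(z[i] + shift * dz))


def thickness_regression(points: Sequence[ThicknessPoint]):
    """OLS of |z_peak| on cholesterol mol%; returns (slope, intercept, r).

    The reported r is the Pearson correlation coefficient of the fit.
    """
    if len(points) < 3:
        raise ValueError("need at least 3 points for a regression")
    x = np.array([p.cholesterol_percent for p in points])
    y = np.array([p.z_peak for p in points])
    if np.allclose(x, x[0]):
        raise ValueError("degenerate regression: no variance in cholesterol content")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue)


def order_parameter(orientations: Mapping[int, Sequence[float]]) -> OrderParameterProfile:
    """S = <3 cos^2 theta - 1>/2 per carbon from bond-orientation cosines."""
    carbons = sorted(orientations)
    svals = []
    for c in carbons:
        cos = np.asarray(orientations[c], dtype=float)
        if cos.size < 1:
            raise ValueError(f"carbon {c} has no orientation samples")
        if np.any(np.abs(cos) > 1.0 + 1e-12):
            raise ValueError(f"carbon {c} has cos(theta) outside [-1, 1]")
        svals.append(0.5 * np.mean(3.0 * cos**2 - 1.0))
    return OrderParameterProfile(carbons=np.array(carbons), S=np.array(svals))


# --------------------------------------------------------------------------
# synthetic fixture generator
# --------------------------------------------------------------------------


def generate_membrane_frames(n_frames: int = 10, area: float = 36.0,
                             headgroup_peak_z: float = 2.1,
                             headgroup_sd: float = 0.25,
                             n_headgroups: int = 60,
                             tail_sd: float = 0.9, n_tails: int = 240,
                             cholesterol_z: float = 1.0,
                             cholesterol_sd: float = 0.5,
                             n_cholesterol: int = 0,
                             seed: int = 0) -> pd.DataFrame:
    """Synthetic particle frames from declared Gaussian mixtures.

    Head groups sit in two symmetric Gaussian sheets at +-headgroup_peak_z,
    tails fill the core, cholesterol (optional) sits between.  Leaflet
    labels follow the sign of z.  Counts are per frame and per leaflet.
    """
    rng = np.random.default_rng(seed)
    rows = []
    specs = [("headgroup", headgroup_peak_z, headgroup_sd, n_headgroups),
             ("tail", 0.0, tail_sd, n_tails),
             ("cholesterol", cholesterol_z, cholesterol_sd, n_cholesterol)]
    for f in range(n_frames):
        for species, mu, sd, n in specs:
            if n <= 0:
                continue
            if mu == 0.0:
                z = rng.normal(0.0, sd, size=n)
            else:
                half = n // 2
                z = np.concatenate([rng.normal(+mu, sd, size=half),
                                    rng.normal(-mu, sd, size=n - half)])
            for zi in z:
                rows.append((f, species, "outer" if zi >= 0 else "inner", zi))
    return pd.DataFrame(rows, columns=list(FRAME_COLUMNS))
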