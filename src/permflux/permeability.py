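"""Resistance profiles and permeability from the solubility-diffusion model.

The local permeation resistance at depth z is R(z) = exp(W(z)/RT) / D(z);
its integral across the membrane is the total resistance, whose
reciprocal is the permeability:

    P = 1 / int_{z1}^{z2} R(z) dz.

Internally everything is in nm/ps/kJ-mol units; the integrated
resistance and the permeability are converted to s/m and m/s exactly
once, at the reporting boundary.  Errors are propagated to first order
treating bins as independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import diffusion as _diffusion
from . import wham as _wham
from .membrane1d import (
    NM_PER_PS_TO_M_PER_S,
    PS_PER_NM_TO_S_PER_M,
    ThermoState,
    WindowSet,
)

logger = logging.getLogger(__name__)

#: 1 ps/nm^2 expressed in s/m^2 (local resistance conversion)
PS_PER_NM2_TO_S_PER_M2 = 1.0e6


@dataclass(frozen=True)
class ResistanceProfile:
    """Local resistance r(z) on the PMF grid, internally in ps/nm^2."""

    z: np.ndarray
    r: np.ndarray
    sigma_r: np.ndarray

    def __post_init__(self) -> None:
        for name in ("z", "r", "sigma_r"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (self.z.size == self.r.size == self.sigma_r.size):
            raise ValueError("z, r and sigma_r must have equal length")

    @property
    def r_si(self) -> np.ndarray:
        """Local resistance in s/m^2."""
        return self.r * PS_PER_NM2_TO_S_PER_M2


@dataclass(frozen=True)
class PermeabilityResult:
    """Total resistance (s/m) and permeability (m/s) with propagated errors."""

    R_total: float
    P: float
    sigma_R: float
    sigma_P: float
    z1: float
    z2: float


def resistance_profile(pmf: _wham.PmfProfile, dprof: _diffusion.DiffusionProfile,
                       thermo: ThermoState) -> ResistanceProfile:
    """Pointwise r(z) = exp(W/RT)/D on the PMF grid.

    D and sigma_D are interpolated linearly onto the PMF grid (D varies
    slowly; W drives r).  sigma_r = r sqrt[(sigma_W/RT)^2 + (sigma_D/D)^2].
    Bins with undefined W propagate as NaN.
    """
    if np.any(pmf.sigma_W[pmf.defined] < 0) or np.any(dprof.sigma_D < 0):
        raise ValueError("input sigmas must be non-negative")
    d = np.interp(pmf.z, dprof.centers, dprof.D)
    sd = np.interp(pmf.z, dprof.centers, dprof.sigma_D)
    if np.any(d <= 0):
        raise ValueError("interpolated D must be positive everywhere")
    rt = thermo.RT
    with np.errstate(invalid="ignore", over="ignore"):
        r = np.exp(pmf.W / rt) / d
        sigma_r = r * np.sqrt((pmf.sigma_W / rt) ** 2 + (sd / d) ** 2)
    return ResistanceProfile(z=pmf.z, r=r, sigma_r=sigma_r)


def _trapezoid_nodes(rprof: ResistanceProfile, z1: float, z2: float):
    """Grid restricted to [z1, z2] with interpolated end nodes + weights."""
    z = rprof.z
    if z1 >= z2:
        raise ValueError("require z1 < z2")
    if z[0] > z1 or z[-1] < z2:
        raise ValueError(
            f"resistance profile [{z[0]:.3f}, {z[-1]:.3f}] does not cover "
            f"the integration limits [{z1}, {z2}]"
        )
    inner = (z > z1) & (z < z2)
    zi = np.concatenate(([z1], z[inner], [z2]))
    ri = np.concatenate(([np.interp(z1, z, rprof.r)], rprof.r[inner],
                         [np.interp(z2, z, rprof.r)]))
    si = np.concatenate(([np.interp(z1, z, rprof.sigma_r)], rprof.sigma_r[inner],
                         [np.interp(z2, z, rprof.sigma_r)]))
    bad = ~np.isfinite(ri)
    if np.any(bad):
        raise ValueError(
            "resistance undefined inside the integration range at z = "
            + ", ".join(f"{v:.3f}" for v in zi[bad][:10])
        )
    # trapezoid weights: w_0 = dz_0/2, w_i = (dz_{i-1}+dz_i)/2, w_m = dz_{m-1}/2
    dz = np.diff(zi)
    w = np.empty_like(zi)
    w[0] = dz[0] / 2.0
    w[-1] = dz[-1] / 2.0
    w[1:-1] = (dz[:-1] + dz[1:]) / 2.0
    return zi, ri, si, w


def integrate_permeability(rprof: ResistanceProfile, z1: float = -2.3,
                           z2: float = 2.3) -> PermeabilityResult:
    """Trapezoidal total resistance over [z1, z2] and its reciprocal.

    The result is insensitive to widening the limits when r is
    negligible outside the membrane; P * R_total = 1 exactly.
    """
    _, ri, si, w = _trapezoid_nodes(rprof, z1, z2)
    r_int = float(np.dot(w, ri))                    # ps/nm
    sigma_int = float(np.sqrt(np.sum((w * si) ** 2)))
    r_total = r_int * PS_PER_NM_TO_S_PER_M          # s/m
    sigma_r_total = sigma_int * PS_PER_NM_TO_S_PER_M
    p = 1.0 / r_total
    return PermeabilityResult(
        R_total=r_total, P=p, sigma_R=sigma_r_total,
        sigma_P=sigma_r_total / r_total**2, z1=z1, z2=z2,
    )


def permeability_from_resistance(r_total: float) -> float:
    """P = 1/R_total with R in s/m, P in m/s."""
    if r_total <= 0:
        raise ValueError("total resistance must be positive")
    return 1.0 / r_total


def propagate_errors(pmf: _wham.PmfProfile, dprof: _diffusion.DiffusionProfile,
                     thermo: ThermoState, z1: float = -2.3, z2: float = 2.3):
    """First-order error propagation from sigma_W and sigma_D.

    Returns (sigma_r per PMF bin in ps/nm^2, sigma_R in s/m, sigma_P in
    m/s) under bin independence.
    """
    rprof = resistance_profile(pmf, dprof, thermo)
    result = integrate_permeability(rprof, z1=z1, z2=z2)
    return rprof.sigma_r, result.sigma_R, result.sigma_P


# --------------------------------------------------------------------------
# end-to-end pipeline
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PipelineResult:
    """Bundle of every stage of the windows -> permeability pipeline."""

    pmf: _wham.PmfProfile
    diffusion: _diffusion.DiffusionProfile
    resistance: ResistanceProfile
    permeability: PermeabilityResult
    settings: dict = field(default_factory=dict)


def compute_permeability(windows: WindowSet, thermo: ThermoState = ThermoState(),
                         *, bin_width: float = 0.02,
                         reference_region=((-2.3, -2.0), (2.0, 2.3)),
                         z1: float = -2.3, z2: float = 2.3,
                         n_boot: int = 0, seed: int = 0,
                         pooled: bool = False, n_blocks: int = 4,
                         max_lag: float | None = None,
                         edge_margin: float = 0.5) -> PipelineResult:
    """Full pipeline: WHAM PMF, force-correlation D(z), resistance, P.

    By default one WHAM is solved per replicate and the referenced PMFs
    are averaged (``pooled=True`` solves a single WHAM over all
    replicates instead).  With ``n_boot > 0`` the PMF error is the
    histogram-level bootstrap sigma; otherwise it is the replicate
    scatter from the averaging step.
    """
    settings = dict(bin_width=bin_width, reference_region=reference_region,
                    z1=z1, z2=z2, n_boot=n_boot, seed=seed, pooled=pooled,
                    n_blocks=n_blocks, max_lag=max_lag,
                    temperature=thermo.temperature)
    logger.info("compute_permeability settings: %s", settings)

    centers = windows.centers
    edges = _wham.make_edges(centers[0] - edge_margin, centers[-1] + edge_margin,
                             bin_width)
    all_hists = [_wham.histogram_window(w, edges) for w in windows.windows]

    try:
        if pooled:
            sol = _wham.solve_wham(all_hists, thermo)
            pmf = _wham.reference_pmf(sol.pmf, reference_region)
        else:
            per_rep = []
            for rep, wins in windows.by_replicate().items():
                hists = [_wham.histogram_window(w, edges) for w in wins]
                sol = _wham.solve_wham(hists, thermo)
                per_rep.append(_wham.reference_pmf(sol.pmf, reference_region))
            pmf = _wham.average_pmfs(per_rep)
        if n_boot > 0:
            sigma_boot = _wham.bootstrap_pmf(
                all_hists, thermo, n_boot=n_boot, seed=seed,
                reference_region=reference_region, allow_degenerate=True,
            )
            pmf = _wham.PmfProfile(z=pmf.z, W=pmf.W, sigma_W=sigma_boot,
                                   reference_convention=pmf.reference_convention)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'wham' failed: {exc}") from exc

    try:
        estimates = [
            _diffusion.estimate_diffusion_blocked(w, thermo, n_blocks=n_blocks,
                                                  max_lag=max_lag)
            for w in windows.windows
        ]
        dprof = _diffusion.diffusion_profile(estimates)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'diffusion' failed: {exc}") from exc

    try:
        rprof = resistance_profile(pmf, dprof, thermo)
        result = integrate_permeability(rprof, z1=z1, z2=z2)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'permeability' failed: {exc}") from exc

    return PipelineResult(pmf=pmf, diffusion=dprof, resistance=rprof,
                          permeability=result, settings=settings)
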