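"""Position-dependent diffusion from the force-correlation method.

For a harmonically restrained permeant, the local diffusion coefficient
follows from the time integral of the autocorrelation of the force
fluctuations,

    D(z) = (RT)^2 / int_0^inf <dF_z(z, t) dF_z(z, 0)> dt,

where dF_z is the instantaneous minus the mean force on the permeant.
The ACF is fitted by a single exponential A exp(-t/tau) prior to
integration, so the integral is taken analytically as A * tau.  Errors
come from splitting each trajectory into four equal blocks and taking
the standard deviation of the per-block estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .membrane1d import ThermoState, UmbrellaWindow


class DiffusionEstimationError(RuntimeError):
    pass


@dataclass(frozen=True)
class AcfSeries:
    """Autocorrelation values on uniform lags starting at 0 ps."""

    lags: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "lags", np.asarray(self.lags, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.lags.size != self.values.size:
            raise ValueError("lags and values must have equal length")
        if self.lags[0] != 0.0:
            raise ValueError("lags must start at 0")


@dataclass(frozen=True)
class DiffusionEstimate:
    """Diffusion coefficient for one window with fit diagnostics."""

    center: float
    D: float
    amplitude: float
    tau: float
    block_sd: float = float("nan")
    replicate_id: str = "rep0"


@dataclass(frozen=True)
class DiffusionProfile:
    """D(z) per window center with combined errors."""

    centers: np.ndarray
    D: np.ndarray
    sigma_D: np.ndarray

    def __post_init__(self) -> None:
        for name in ("centers", "D", "sigma_D"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(np.diff(self.centers) <= 0):
            raise ValueError("centers must be strictly increasing")
        if np.any(self.D <= 0):
            raise ValueError("D must be positive")


# --------------------------------------------------------------------------


def force_fluctuation_acf(window: UmbrellaWindow, max_lag: float | None = None) -> AcfSeries:
    """Biased (1/N) autocorrelation of the force fluctuations.

    ``max_lag`` is in ps and defaults to one tenth of the window
    duration — long enough to capture the decay while excluding the
    noisy tail.
    """
    if window.n_samples < 10:
        raise ValueError("need at least 10 samples for an ACF")
    dt = window.timestep_between_samples
    if max_lag is None:
        max_lag = window.duration / 10.0
    if max_lag >= window.duration:
        raise ValueError("max_lag must be shorter than the window duration")
    n_lag = max(1, int(round(max_lag / dt)))
    f = window.forces - window.forces.mean()
    n = f.size
    # FFT-based autocovariance with the biased 1/N normalization
    m = 1 << int(np.ceil(np.log2(2 * n)))
    fhat = np.fft.rfft(f, m)
    acov = np.fft.irfft(fhat * np.conj(fhat), m)[: n_lag + 1] / n
    return AcfSeries(lags=dt * np.arange(n_lag + 1), values=acov)


def fit_single_exponential(acf: AcfSeries) -> tuple:
    """Least-squares fit of A exp(-t/tau); returns (A, tau).

    The fit runs from lag 0 up to the first lag where the ACF drops
    below A0 * e^-3 (or the end of the series).  Initial guesses are
    A = acf(0) and tau = the first 1/e crossing.
    """
    a0 = acf.values[0]
    if a0 <= 0:
        raise DiffusionEstimationError("ACF at lag 0 must be positive")
    below = np.nonzero(acf.values < a0 * np.exp(-3.0))[0]
    stop = int(below[0]) + 1 if below.size else acf.lags.size
    t = acf.lags[:stop]
    y = acf.values[:stop]
    cross = np.nonzero(y < a0 / np.e)[0]
    tau0 = float(t[cross[0]]) if cross.size else float(max(t[-1] / 2.0, t[1] if t.size > 1 else 1.0))
    tau0 = max(tau0, float(t[1]) if t.size > 1 else 1e-6)
    try:
        popt, _ = curve_fit(
            lambda tt, a, tau: a * np.exp(-tt / tau), t, y,
            p0=(a0, tau0), bounds=([0.0, 1e-12], [np.inf, np.inf]), maxfev=10_000,
        )
    except (RuntimeError, ValueError) as exc:
        raise DiffusionEstimationError(
            f"single-exponential ACF fit failed over {stop} lags "
            f"(A0={a0:.3g}, tau0={tau0:.3g}): {exc}"
        ) from exc
    return float(popt[0]), float(popt[1])


def estimate_diffusion(window: UmbrellaWindow, thermo: ThermoState,
                       max_lag: float | None = None) -> DiffusionEstimate:
    """Single-trajectory D = RT^2 / (A tau) in nm^2/ps."""
    acf = force_fluctuation_acf(window, max_lag=max_lag)
    a, tau = fit_single_exponential(acf)
    if a * tau <= 0:
        raise DiffusionEstimationError("non-positive ACF integral")
    d = thermo.RT**2 / (a * tau)
    return DiffusionEstimate(center=window.center, D=d, amplitude=a, tau=tau,
                             replicate_id=window.replicate_id)


def _split_blocks(window: UmbrellaWindow, n_blocks: int) -> list:
    n = window.n_samples // n_blocks
    if n < 10:
        raise ValueError(
            f"window too short to split into {n_blocks} blocks of >= 10 samples"
        )
    out = []
    for b in range(n_blocks):
        out.append(
            dc_replace(window, positions=window.positions[b * n:(b + 1) * n],
                       forces=window.forces[b * n:(b + 1) * n])
        )
    return out


def block_estimates(window: UmbrellaWindow, thermo: ThermoState,
                    n_blocks: int = 4, max_lag: float | None = None) -> list:
    """Independent D estimates on contiguous equal blocks of the trajectory."""
    return [estimate_diffusion(b, thermo, max_lag=max_lag)
            for b in _split_blocks(window, n_blocks)]


def block_sd(window: UmbrellaWindow, thermo: ThermoState, n_blocks: int = 4,
             max_lag: float | None = None) -> float:
    """Standard deviation of the per-block D values (the reported error)."""
    ds = [e.D for e in block_estimates(window, thermo, n_blocks, max_lag)]
    return float(np.std(ds, ddof=1))


def estimate_diffusion_blocked(window: UmbrellaWindow, thermo: ThermoState,
                               n_blocks: int = 4,
                               max_lag: float | None = None) -> DiffusionEstimate:
    """Blocked estimate: D is the mean of the per-block values, the error
    their standard deviation."""
    blocks = block_estimates(window, thermo, n_blocks, max_lag)
    ds = np.array([e.D for e in blocks])
    return DiffusionEstimate(
        center=window.center, D=float(ds.mean()),
        amplitude=float(np.mean([e.amplitude for e in blocks])),
        tau=float(np.mean([e.tau for e in blocks])),
        block_sd=float(ds.std(ddof=1)), replicate_id=window.replicate_id,
    )


def diffusion_profile(estimates: Sequence[DiffusionEstimate]) -> DiffusionProfile:
    """Average replicate estimates per window center.

    sigma combines the replicate scatter with the per-estimate block
    errors in quadrature: sigma^2 = s_replicates^2 + mean(block_sd^2).
    """
    if not estimates:
        raise ValueError("need at least one estimate")
    groups: dict = {}
    for e in estimates:
        groups.setdefault(round(e.center, 9), []).append(e)
    centers, dvals, sigmas = [], [], []
    for c in sorted(groups):
        ds = np.array([e.D for e in groups[c]])
        bsd = np.array([e.block_sd for e in groups[c]])
        scatter = ds.std(ddof=1) if ds.size > 1 else 0.0
        block_term = np.mean(bsd**2) if np.all(np.isfinite(bsd)) else 0.0
        centers.append(c)
        dvals.append(ds.mean())
        sigmas.append(np.sqrt(scatter**2 + block_term))
    return DiffusionProfile(centers=np.array(centers), D=np.array(dvals),
                            sigma_D=np.array(sigmas))
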