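"""One-dimensional membrane landscapes and overdamped Brownian dynamics.

This module is the physical oracle for the permeability pipeline.  It
provides smooth parametric free-energy / diffusivity landscapes W(z), D(z)
for a permeant crossing a lipid bilayer, biased (umbrella) Langevin
sampling of those landscapes, a reference permeability by quadrature of
the inhomogeneous solubility-diffusion integrand exp(W/RT)/D, and a
brute-force first-passage oracle.

Units are nm, ps and kJ/mol throughout; conversion to SI (m/s, m^2/s)
happens only at reporting boundaries via the exported constants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from numba import njit

# --------------------------------------------------------------------------
# constants & thermodynamic state
# --------------------------------------------------------------------------

#: molar gas constant in kJ mol^-1 K^-1
GAS_CONSTANT = 8.314462e-3

#: 1 nm/ps expressed in m/s (permeability conversion)
NM_PER_PS_TO_M_PER_S = 1.0e3

#: 1 nm^2/ps expressed in m^2/s (diffusivity conversion)
NM2_PER_PS_TO_M2_PER_S = 1.0e-6

#: 1 ps/nm expressed in s/m (integrated resistance conversion)
PS_PER_NM_TO_S_PER_M = 1.0e-3


@dataclass(frozen=True)
class ThermoState:
    """Temperature and the derived thermal energy scale RT (kJ/mol)."""

    temperature: float = 320.0
    molar_gas_constant: float = GAS_CONSTANT

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def RT(self) -> float:
        return self.molar_gas_constant * self.temperature


# --------------------------------------------------------------------------
# ground-truth landscape
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GroundTruthModel:
    """Smooth parametric membrane landscape with analytic derivatives.

    The free-energy profile is a central Gaussian barrier plus optional
    symmetric Gaussian interfacial wells; it is shifted by a constant so
    that W(+-half_width) = 0 exactly.  The diffusivity interpolates
    smoothly between a bulk (water) value and a slower core value through
    a central Gaussian dip.  Both profiles are C^infinity, as required by
    the D'(z) drift term of the overdamped dynamics.

    Parameters
    ----------
    half_width
        Landscape support is [-half_width, half_width] (nm).
    barrier_height, barrier_width
        Height (kJ/mol) and Gaussian standard deviation (nm) of the
        central barrier.
    well_depth, well_position, well_width
        Optional symmetric interfacial wells (kJ/mol, nm, nm).
    bulk_diffusivity, core_diffusivity
        D in water and in the membrane core (nm^2/ps).
    diffusivity_transition_width
        Gaussian width (nm) of the central diffusivity dip.
    """

    half_width: float = 2.6
    barrier_height: float = 62.0
    barrier_width: float = 0.4
    well_depth: float = 0.0
    well_position: float = 1.8
    well_width: float = 0.2
    bulk_diffusivity: float = 5.0e-3
    core_diffusivity: float = 1.0e-3
    diffusivity_transition_width: float = 0.5

    def __post_init__(self) -> None:
        for name in ("half_width", "barrier_width", "well_width",
                     "diffusivity_transition_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.barrier_height < 0:
            raise ValueError("barrier_height must be non-negative")
        if self.bulk_diffusivity <= 0 or self.core_diffusivity <= 0:
            raise ValueError("diffusivities must be positive")

    # -- raw (unshifted) potential -----------------------------------------
    def _raw_potential(self, z):
        z = np.asarray(z, dtype=float)
        w = self.barrier_height * np.exp(-z**2 / (2.0 * self.barrier_width**2))
        if self.well_depth != 0.0:
            sw2 = 2.0 * self.well_width**2
            w = w - self.well_depth * (
                np.exp(-((z - self.well_position) ** 2) / sw2)
                + np.exp(-((z + self.well_position) ** 2) / sw2)
            )
        return w

    def potential(self, z):
        """W(z) in kJ/mol, with W(+-half_width) = 0 exactly."""
        return self._raw_potential(z) - self._raw_potential(self.half_width)

    def potential_grad(self, z):
        """dW/dz in kJ/mol/nm."""
        z = np.asarray(z, dtype=float)
        g = (-z / self.barrier_width**2) * self.barrier_height * np.exp(
            -z**2 / (2.0 * self.barrier_width**2)
        )
        if self.well_depth != 0.0:
            sw2 = self.well_width**2
            for sign in (+1.0, -1.0):
                x = z - sign * self.well_position
                g = g + self.well_depth * (x / sw2) * np.exp(-x**2 / (2.0 * sw2))
        return g

    def diffusivity(self, z):
        """D(z) in nm^2/ps; strictly positive."""
        z = np.asarray(z, dtype=float)
        dip = np.exp(-z**2 / (2.0 * self.diffusivity_transition_width**2))
        return self.bulk_diffusivity - (self.bulk_diffusivity - self.core_diffusivity) * dip

    def diffusivity_grad(self, z):
        """dD/dz in nm/ps."""
        z = np.asarray(z, dtype=float)
        s2 = self.diffusivity_transition_width**2
        dip = np.exp(-z**2 / (2.0 * s2))
        return (self.bulk_diffusivity - self.core_diffusivity) * (z / s2) * dip

    def _params(self) -> np.ndarray:
        """Pack parameters for the compiled integrator kernels."""
        return np.array(
            [
                self.barrier_height,
                self.barrier_width,
                self.well_depth,
                self.well_position,
                self.well_width,
                self.bulk_diffusivity,
                self.core_diffusivity,
                self.diffusivity_transition_width,
                self.half_width,
            ],
            dtype=np.float64,
        )


_PRESETS = {
    # barrier heights mirror the reported PMF ladder for cisplatin:
    # pure DOPC ~40 kJ/mol, realistic asymmetric membrane without
    # cholesterol ~62 kJ/mol, with 33% cholesterol ~70 kJ/mol.
    "dopc-like": dict(barrier_height=40.0, core_diffusivity=2.0e-3),
    "normal-0chl-like": dict(barrier_height=62.0, core_diffusivity=1.0e-3),
    "normal-33chl-like": dict(barrier_height=70.0, barrier_width=0.45,
                              core_diffusivity=1.0e-3),
    "flat": dict(barrier_height=0.0, core_diffusivity=5.0e-3,
                 bulk_diffusivity=5.0e-3),
}


def make_membrane_model(preset: str | None = None, **overrides) -> GroundTruthModel:
    """Build a membrane landscape from a named preset and/or explicit values.

    Presets: ``dopc-like`` (40 kJ/mol barrier), ``normal-0chl-like``
    (62 kJ/mol), ``normal-33chl-like`` (70 kJ/mol), ``flat`` (W == 0,
    uniform D).  Explicit keyword parameters override preset values.
    """
    params: dict = {}
    if preset is not None:
        try:
            params.update(_PRESETS[preset])
        except KeyError:
            raise ValueError(
                f"unknown preset {preset!r}; choose from {sorted(_PRESETS)}"
            ) from None
    params.update(overrides)
    return GroundTruthModel(**params)


# --------------------------------------------------------------------------
# reference permeability (quadrature of the ISD integral)
# --------------------------------------------------------------------------


def reference_permeability(model, thermo: ThermoState, z1: float = -2.3,
                           z2: float = 2.3, n_quad: int = 20001) -> float:
    """Ground-truth permeability in m/s by trapezoidal quadrature.

    Evaluates P = 1 / int_{z1}^{z2} exp(W(z)/RT) / D(z) dz on a fine
    uniform grid.  Any object exposing ``potential(z)`` and
    ``diffusivity(z)`` (vectorized, nm / kJ/mol / nm^2/ps) is accepted.
    """
    if not z1 < z2:
        raise ValueError("require z1 < z2")
    if n_quad < 1000:
        raise ValueError("n_quad must be at least 1000")
    z = np.linspace(z1, z2, int(n_quad))
    d = np.asarray(model.diffusivity(z), dtype=float)
    if np.any(d <= 0):
        raise ValueError("diffusivity must be positive over the integration range")
    integrand = np.exp(np.asarray(model.potential(z), dtype=float) / thermo.RT) / d
    r_total = np.trapezoid(integrand, z)          # ps/nm
    return (1.0 / r_total) * NM_PER_PS_TO_M_PER_S


# --------------------------------------------------------------------------
# umbrella windows and Langevin sampling
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class LangevinConfig:
    """Integration settings for the overdamped Euler-Maruyama sampler.

    ``timestep`` (ps) must keep k_u * dt * D / RT well below 1; the
    default satisfies the < 0.05 rule for k_u = 1000 kJ/mol/nm^2 and
    D = 5e-3 nm^2/ps.  Identical seeds give bit-identical trajectories.
    """

    timestep: float = 0.01
    n_steps: int = 200_000
    equilibration_steps: int = 20_000
    sample_stride: int = 1
    seed: int = 0
    stochastic_convention: str = "Ito-with-drift-correction"

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.sample_stride < 1:
            raise ValueError("sample_stride must be >= 1")
        if self.n_steps < self.sample_stride:
            raise ValueError("n_steps must be >= sample_stride")


@dataclass(frozen=True)
class UmbrellaWindow:
    """One biased sampling window: restraint parameters plus time series.

    ``forces`` holds the total systematic force on the permeant along z,
    F = -W'(z) - k_u (z - z0), in kJ/mol/nm, sampled at the same times
    as ``positions``.
    """

    center: float
    spring_constant: float
    positions: np.ndarray
    forces: np.ndarray
    timestep_between_samples: float
    replicate_id: str = "rep0"

    def __post_init__(self) -> None:
        if self.spring_constant <= 0:
            raise ValueError("spring_constant must be positive")
        object.__setattr__(self, "positions", np.asarray(self.positions, dtype=float))
        object.__setattr__(self, "forces", np.asarray(self.forces, dtype=float))
        if self.positions.shape != self.forces.shape:
            raise ValueError("positions and forces must have equal length")
        if self.positions.size < 2:
            raise ValueError("a window needs at least 2 samples")
        if self.timestep_between_samples <= 0:
            raise ValueError("timestep_between_samples must be positive")

    @property
    def n_samples(self) -> int:
        return int(self.positions.size)

    @property
    def duration(self) -> float:
        """Sampled span in ps."""
        return (self.n_samples - 1) * self.timestep_between_samples


@dataclass(frozen=True)
class WindowSet:
    """Ordered collection of umbrella windows, possibly replicated."""

    windows: tuple
    spacing: float = 0.1

    def __post_init__(self) -> None:
        object.__setattr__(self, "windows", tuple(self.windows))
        for rep in self.replicate_ids:
            cs = [w.center for w in self.windows if w.replicate_id == rep]
            if any(b <= a for a, b in zip(cs, cs[1:])):
                raise ValueError(
                    f"window centers must be strictly increasing within replicate {rep!r}"
                )

    @property
    def replicate_ids(self) -> list:
        seen = []
        for w in self.windows:
            if w.replicate_id not in seen:
                seen.append(w.replicate_id)
        return seen

    @property
    def centers(self) -> np.ndarray:
        return np.unique([w.center for w in self.windows])

    def by_replicate(self) -> dict:
        return {rep: [w for w in self.windows if w.replicate_id == rep]
                for rep in self.replicate_ids}

    def __len__(self) -> int:
        return len(self.windows)


# -- compiled kernels -------------------------------------------------------


@njit(cache=True)
def _force_and_d(z, p):
    """Return (dW/dz, D, dD/dz) at scalar z for packed parameters p."""
    w0, bw, ed, zw, sw, dw, dm, sd, _L = p[0], p[1], p[2], p[3], p[4], p[5], p[6], p[7], p[8]
    dwdz = (-z / (bw * bw)) * w0 * math.exp(-z * z / (2.0 * bw * bw))
    if ed != 0.0:
        for sign in (1.0, -1.0):
            x = z - sign * zw
            dwdz += ed * (x / (sw * sw)) * math.exp(-x * x / (2.0 * sw * sw))
    dip = math.exp(-z * z / (2.0 * sd * sd))
    d = dw - (dw - dm) * dip
    dddz = (dw - dm) * (z / (sd * sd)) * dip
    return dwdz, d, dddz


@njit(cache=True)
def _langevin_window_kernel(p, rt, z0, ku, dt, n_steps, equil, stride, seed):
    """Euler-Maruyama integration of the biased overdamped dynamics.

    dz = [-D (W' + k_u (z - z0)) / RT + D'] dt + sqrt(2 D dt) xi,
    with reflection at +-half_width.  Returns sampled (positions, forces);
    the recorded force is the total systematic force -W' - k_u (z - z0).
    """
    np.random.seed(seed)
    L = p[8]
    z = z0
    n_out = n_steps // stride
    pos = np.empty(n_out)
    frc = np.empty(n_out)
    j = 0
    total = equil + n_steps
    for i in range(total):
        dwdz, d, dddz = _force_and_d(z, p)
        f = -dwdz - ku * (z - z0)
        if i >= equil and (i - equil) % stride == 0 and j < n_out:
            pos[j] = z
            frc[j] = f
            j += 1
        z += (d * f / rt + dddz) * dt + math.sqrt(2.0 * d * dt) * np.random.normal()
        if z > L:
            z = 2.0 * L - z
        elif z < -L:
            z = -2.0 * L - z
    return pos, frc


@njit(cache=True)
def _first_passage_kernel(p, rt, dt, start, absorbing, reflecting, n_particles,
                          max_steps, seed):
    """Per-particle first-passage times (ps) to the absorbing boundary."""
    np.random.seed(seed)
    out = np.empty(n_particles)
    up = absorbing > reflecting
    for n in range(n_particles):
        z = start
        steps = 0
        while steps < max_steps:
            if (up and z >= absorbing) or ((not up) and z <= absorbing):
                break
            dwdz, d, dddz = _force_and_d(z, p)
            z += (-d * dwdz / rt + dddz) * dt + math.sqrt(2.0 * d * dt) * np.random.normal()
            if up and z < reflecting:
                z = 2.0 * reflecting - z
            elif (not up) and z > reflecting:
                z = 2.0 * reflecting - z
            steps += 1
        if steps >= max_steps:
            out[n] = -1.0
        else:
            out[n] = steps * dt
    return out


def _step_size_check(model: GroundTruthModel, k_u: float, config: LangevinConfig,
                     thermo: ThermoState) -> None:
    dmax = max(model.bulk_diffusivity, model.core_diffusivity)
    if k_u > 0 and k_u * config.timestep * dmax / thermo.RT > 0.5:
        raise ValueError(
            "timestep too large for this umbrella stiffness: "
            "k_u * dt * D / RT must stay well below 1; decrease the timestep"
        )
    # typical displacement per step must stay below half the barrier width
    typ = 4.0 * math.sqrt(2.0 * dmax * config.timestep)
    if typ > model.barrier_width / 2.0:
        raise ValueError(
            f"timestep {config.timestep} ps gives per-step displacements "
            f"~{typ:.3g} nm, larger than half the barrier width "
            f"({model.barrier_width / 2:.3g} nm); decrease the timestep"
        )


def simulate_window(model: GroundTruthModel, z0: float, k_u: float,
                    config: LangevinConfig, thermo: ThermoState,
                    replicate_id: str = "rep0") -> UmbrellaWindow:
    """Sample one umbrella window by overdamped Brownian dynamics.

    The long-run position histogram converges to the biased Boltzmann
    density ~ exp(-[W(z) + k_u (z - z0)^2 / 2] / RT); the Ito drift
    correction D'(z) makes this hold for position-dependent D.
    """
    if not -model.half_width <= z0 <= model.half_width:
        raise ValueError("window center outside the model support")
    if k_u <= 0:
        raise ValueError("spring constant must be positive")
    _step_size_check(model, k_u, config, thermo)
    pos, frc = _langevin_window_kernel(
        model._params(), thermo.RT, float(z0), float(k_u), config.timestep,
        config.n_steps, config.equilibration_steps, config.sample_stride,
        int(config.seed) % 2**31,
    )
    return UmbrellaWindow(
        center=float(z0), spring_constant=float(k_u), positions=pos, forces=frc,
        timestep_between_samples=config.timestep * config.sample_stride,
        replicate_id=replicate_id,
    )


def simulate_free(model: GroundTruthModel, z0: float, config: LangevinConfig,
                  thermo: ThermoState) -> np.ndarray:
    """Unbiased trajectory (no umbrella); returns sampled positions."""
    pos, _ = _langevin_window_kernel(
        model._params(), thermo.RT, float(z0), 0.0, config.timestep,
        config.n_steps, config.equilibration_steps, config.sample_stride,
        int(config.seed) % 2**31,
    )
    return pos


def generate_window_set(model: GroundTruthModel, z_min: float, z_max: float,
                        spacing: float = 0.1, k_u: float = 1000.0,
                        n_replicates: int = 1,
                        config: LangevinConfig = LangevinConfig(),
                        thermo: ThermoState = ThermoState()) -> WindowSet:
    """Ladder of umbrella windows every ``spacing`` nm, optionally replicated.

    Centers are z_min, z_min + spacing, ...; the count per replicate is
    floor((z_max - z_min)/spacing) + 1.  Each window gets an independent
    stream derived from ``config.seed`` so the whole set is reproducible.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if not z_min < z_max:
        raise ValueError("require z_min < z_max")
    n_win = int(math.floor((z_max - z_min) / spacing + 1e-9)) + 1
    centers = z_min + spacing * np.arange(n_win)
    root = np.random.SeedSequence(int(config.seed))
    streams = root.spawn(n_replicates * n_win)
    windows = []
    k = 0
    for rep in range(n_replicates):
        for z0 in centers:
            seed = int(streams[k].generate_state(1)[0] % 2**31)
            k += 1
            cfg = replace(config, seed=seed)
            windows.append(
                simulate_window(model, float(z0), k_u, cfg, thermo,
                                replicate_id=f"rep{rep}")
            )
    return WindowSet(windows=tuple(windows), spacing=spacing)


# --------------------------------------------------------------------------
# first-passage oracle
# --------------------------------------------------------------------------


def mfpt_quadrature(model, thermo: ThermoState, start: float, absorbing: float,
                    reflecting: float, n_quad: int = 4001) -> float:
    """Closed-form mean first-passage time (ps) by double quadrature.

    MFPT = int_start^absorbing dz exp(W(z)/RT)/D(z)
           int_reflecting^z dz' exp(-W(z')/RT).
    """
    if start == absorbing:
        return 0.0
    rt = thermo.RT
    # inner cumulative integral of exp(-W/RT) from the reflecting wall
    zs = np.linspace(reflecting, absorbing, int(n_quad))
    inner = np.exp(-np.asarray(model.potential(zs), dtype=float) / rt)
    from scipy.integrate import cumulative_trapezoid

    cum = cumulative_trapezoid(inner, zs, initial=0.0)
    outer = (
        np.exp(np.asarray(model.potential(zs), dtype=float) / rt)
        / np.asarray(model.diffusivity(zs), dtype=float)
    ) * cum
    i0 = int(np.argmin(np.abs(zs - start)))
    return abs(np.trapezoid(outer[i0:], zs[i0:]))


def first_passage_time(model: GroundTruthModel, thermo: ThermoState,
                       config: LangevinConfig, start: float, absorbing: float,
                       reflecting: float, n_particles: int,
                       max_steps: int = 50_000_000) -> tuple:
    """Stochastic mean first-passage time and its standard error (ps)."""
    if n_particles < 2:
        raise ValueError("n_particles must be at least 2")
    lo, hi = sorted((reflecting, absorbing))
    if not lo <= start <= hi:
        raise ValueError("start must lie between the reflecting and absorbing boundaries")
    if start == absorbing:
        return 0.0, 0.0
    times = _first_passage_kernel(
        model._params(), thermo.RT, config.timestep, float(start),
        float(absorbing), float(reflecting), int(n_particles), int(max_steps),
        int(config.seed) % 2**31,
    )
    if np.any(times < 0):
        raise RuntimeError("some particles were not absorbed within max_steps")
    return float(np.mean(times)), float(np.std(times, ddof=1) / math.sqrt(n_particles))


# --------------------------------------------------------------------------
# synthetic uptake kinetics
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class UptakeSeries:
    """Uptake-versus-time record, as a fraction of the plateau by default."""

    times: np.ndarray
    values: np.ndarray
    fraction_of_plateau: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.times.size != self.values.size:
            raise ValueError("times and values must have equal length")
        if self.times.size < 3:
            raise ValueError("an uptake series needs at least 3 points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


def simulate_uptake(k: float, times: Sequence[float], noise_sd: float = 0.0,
                    seed: int = 0) -> UptakeSeries:
    """First-order uptake 1 - exp(-k t) plus independent Gaussian noise."""
    if k <= 0:
        raise ValueError("rate constant k must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    t = np.asarray(times, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    values = 1.0 - np.exp(-k * t)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, size=t.size)
    return UptakeSeries(times=t, values=values)
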