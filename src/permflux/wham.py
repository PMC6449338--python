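"""Weighted histogram analysis: biased window histograms -> W(z).

Implements the self-consistent WHAM fixed point

    rho(b) = sum_i n_i(b) / sum_i N_i exp[(f_i - u_i(z_b)) / RT]
    f_i    = -RT ln sum_b rho(b) exp(-u_i(z_b) / RT)

with harmonic biases u_i(z) = k_i (z - z0_i)^2 / 2, followed by
referencing (W = 0 on average over a declared region), replicate
averaging, and histogram-level bootstrap errors in which each draw picks
one complete histogram per window center.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace as dc_replace
from typing import Iterable, Sequence

import numpy as np

from .membrane1d import ThermoState, UmbrellaWindow

logger = logging.getLogger(__name__)


class WhamConvergenceError(RuntimeError):
    """Raised when the WHAM iteration fails to reach tolerance."""

    def __init__(self, residual: float, max_iter: int):
        self.residual = residual
        self.max_iter = max_iter
        super().__init__(
            f"WHAM did not converge in {max_iter} iterations "
            f"(residual {residual:.3e} kJ/mol)"
        )


# --------------------------------------------------------------------------
# data containers
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class WindowHistogram:
    """Binned positions of one umbrella window plus its bias parameters."""

    edges: np.ndarray
    counts: np.ndarray
    center: float
    spring_constant: float
    replicate_id: str = "rep0"

    def __post_init__(self) -> None:
        object.__setattr__(self, "edges", np.asarray(self.edges, dtype=float))
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=np.int64))
        if self.edges.size != self.counts.size + 1:
            raise ValueError("need len(edges) == len(counts) + 1")
        widths = np.diff(self.edges)
        if np.any(widths <= 0):
            raise ValueError("edges must be strictly increasing")
        if not np.allclose(widths, widths[0], rtol=1e-6):
            raise ValueError("edges must be uniform")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


@dataclass(frozen=True)
class PmfProfile:
    """W(z) on a uniform grid, NaN where the aggregate counts vanish."""

    z: np.ndarray
    W: np.ndarray
    sigma_W: np.ndarray
    reference_convention: str = "unreferenced"

    def __post_init__(self) -> None:
        for name in ("z", "W", "sigma_W"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (self.z.size == self.W.size == self.sigma_W.size):
            raise ValueError("z, W and sigma_W must have equal length")

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.W)


@dataclass(frozen=True)
class WhamSolution:
    """Converged WHAM output: profile, window free energies, diagnostics."""

    pmf: PmfProfile
    window_free_energies: np.ndarray
    iterations: int
    residual: float


# --------------------------------------------------------------------------
# histogramming
# --------------------------------------------------------------------------


def histogram_window(window: UmbrellaWindow, edges, clip: bool = False) -> WindowHistogram:
    """Bin one window's positions on the given uniform edges.

    Samples outside the edges raise an error naming the offending window
    unless ``clip=True``, in which case they are dropped.
    """
    edges = np.asarray(edges, dtype=float)
    pos = window.positions
    inside = (pos >= edges[0]) & (pos <= edges[-1])
    if not clip and not np.all(inside):
        raise ValueError(
            f"window at z0={window.center} ({window.replicate_id}) has "
            f"{int((~inside).sum())} samples outside [{edges[0]}, {edges[-1]}]; "
            "extend the edges or pass clip=True"
        )
    counts, _ = np.histogram(pos[inside], bins=edges)
    return WindowHistogram(
        edges=edges, counts=counts, center=window.center,
        spring_constant=window.spring_constant, replicate_id=window.replicate_id,
    )


def make_edges(z_min: float, z_max: float, bin_width: float = 0.02) -> np.ndarray:
    """Uniform bin edges covering [z_min, z_max] at the given width."""
    n = int(round((z_max - z_min) / bin_width))
    return z_min + bin_width * np.arange(n + 1)


# --------------------------------------------------------------------------
# the WHAM fixed point
# --------------------------------------------------------------------------


def _check_common_edges(histograms: Sequence[WindowHistogram]) -> np.ndarray:
    edges = histograms[0].edges
    for h in histograms[1:]:
        if h.edges.size != edges.size or not np.allclose(h.edges, edges):
            raise ValueError("all histograms must share identical bin edges")
    return edges


def solve_wham(histograms: Sequence[WindowHistogram], thermo: ThermoState,
               tol: float = 1e-6, max_iter: int = 100_000,
               f_init: np.ndarray | None = None) -> WhamSolution:
    """Iterate the WHAM equations to self-consistency.

    Stops when max_i |Delta f_i| <= tol (kJ/mol).  Bins with zero
    aggregate counts get W = NaN.  The gauge is fixed by f_0 = 0.
    """
    histograms = list(histograms)
    if not histograms:
        raise ValueError("need at least one histogram")
    edges = _check_common_edges(histograms)
    centers = 0.5 * (edges[:-1] + edges[1:])
    rt = thermo.RT

    counts = np.stack([h.counts for h in histograms])        # (n_win, n_bins)
    m_b = counts.sum(axis=0).astype(float)
    active = m_b > 0
    if not np.any(active):
        raise ValueError("all bins are empty")
    n_i = counts.sum(axis=1).astype(float)

    z = centers[active]
    z0 = np.array([h.center for h in histograms])[:, None]
    ku = np.array([h.spring_constant for h in histograms])[:, None]
    bias = 0.5 * ku * (z[None, :] - z0) ** 2                 # (n_win, n_act)
    c = np.exp(-bias / rt)                                   # underflow -> 0 is fine

    g = np.zeros(len(histograms)) if f_init is None else np.asarray(f_init) / rt
    m_act = m_b[active]
    residual = np.inf
    for it in range(1, max_iter + 1):
        denom = (n_i * np.exp(g)) @ c                        # (n_act,)
        rho = m_act / denom
        with np.errstate(divide="ignore"):
            g_new = -np.log(c @ rho)
        g_new -= g_new[0]
        residual = rt * float(np.max(np.abs(g_new - g)))
        g = g_new
        if residual <= tol:
            break
    else:
        raise WhamConvergenceError(residual, max_iter)

    # normalize the unbiased density, then convert to a free energy
    dz = edges[1] - edges[0]
    rho = m_act / ((n_i * np.exp(g)) @ c)
    rho = rho / (rho.sum() * dz)
    w = np.full(centers.size, np.nan)
    w[active] = -rt * np.log(rho)
    pmf = PmfProfile(z=centers, W=w, sigma_W=np.zeros_like(w),
                     reference_convention="unreferenced")
    return WhamSolution(pmf=pmf, window_free_energies=rt * g,
                        iterations=it, residual=residual)


# --------------------------------------------------------------------------
# referencing & averaging
# --------------------------------------------------------------------------


def _region_mask(z: np.ndarray, region) -> np.ndarray:
    """Boolean mask for one (lo, hi) interval or a sequence of them."""
    region = np.asarray(region, dtype=float)
    if region.ndim == 1:
        region = region[None, :]
    mask = np.zeros(z.size, dtype=bool)
    for lo, hi in region:
        mask |= (z >= lo) & (z <= hi)
    return mask


def reference_pmf(profile: PmfProfile, region) -> PmfProfile:
    """Shift W so its mean over the reference region is zero.

    ``region`` is a (lo, hi) interval in nm, or a sequence of intervals
    (e.g. both bulk-water slabs of a symmetric profile).  Idempotent;
    sigma_W is unchanged.
    """
    mask = _region_mask(profile.z, region) & profile.defined
    if mask.sum() < 2:
        raise ValueError("reference region overlaps fewer than 2 defined bins")
    offset = float(np.mean(profile.W[mask]))
    return dc_replace(profile, W=profile.W - offset,
                      reference_convention="zero-mean-region")


def average_pmfs(profiles: Sequence[PmfProfile]) -> PmfProfile:
    """Pointwise mean over replicate profiles.

    The reported sigma combines the pointwise standard deviation across
    replicates with the per-profile sigmas in quadrature:
    sigma^2 = s_replicates^2 + mean(sigma_i^2).  Bins undefined in any
    replicate are undefined in the mean.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    z = profiles[0].z
    conv = profiles[0].reference_convention
    for p in profiles[1:]:
        if p.z.size != z.size or not np.allclose(p.z, z):
            raise ValueError("profiles must share an identical grid")
        if p.reference_convention != conv:
            raise ValueError("profiles must share the reference convention")
    wmat = np.stack([p.W for p in profiles])
    smat = np.stack([p.sigma_W for p in profiles])
    n = wmat.shape[0]
    mean = wmat.mean(axis=0)
    scatter = wmat.std(axis=0, ddof=1) if n > 1 else np.zeros_like(mean)
    sigma = np.sqrt(scatter**2 + np.mean(smat**2, axis=0))
    return PmfProfile(z=z, W=mean, sigma_W=sigma, reference_convention=conv)


# --------------------------------------------------------------------------
# bootstrap
# --------------------------------------------------------------------------


def _group_by_center(histograms: Iterable[WindowHistogram]) -> dict:
    groups: dict = {}
    for h in histograms:
        groups.setdefault(round(h.center, 9), []).append(h)
    return dict(sorted(groups.items()))


def _multinomial_resample(h: WindowHistogram, rng) -> WindowHistogram:
    new_counts = rng.multinomial(h.n_total, h.counts / h.n_total)
    return dc_replace(h, counts=new_counts)


def bootstrap_pmf(histograms: Sequence[WindowHistogram], thermo: ThermoState,
                  n_boot: int = 400, seed: int = 0,
                  reference_region=None, tol: float = 1e-6,
                  max_iter: int = 100_000,
                  allow_degenerate: bool = False) -> np.ndarray:
    """Per-bin bootstrap standard deviation of the referenced PMF.

    For each of ``n_boot`` draws, one complete histogram is drawn with
    replacement from the replicates at every window center (complete
    histograms are the independent data points); WHAM and referencing
    are re-run per draw, and the per-bin standard deviation across the
    draws is returned.  Centers with a single replicate fall back to
    multinomial resampling of that histogram's counts when
    ``allow_degenerate`` is set, with a logged warning.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    groups = _group_by_center(histograms)
    single = [c for c, g in groups.items() if len(g) == 1]
    if single and not allow_degenerate:
        raise ValueError(
            f"{len(single)} window centers have a single replicate; pass "
            "allow_degenerate=True to resample their counts multinomially"
        )
    if single:
        logger.warning(
            "bootstrap: %d centers have one replicate; using multinomial "
            "count resampling there", len(single),
        )
    rng = np.random.default_rng(seed)
    # warm start every draw from the full-data solution
    full = solve_wham(list(histograms), thermo, tol=tol, max_iter=max_iter)
    # the full solution uses all replicates; a draw uses one histogram per
    # center, so map warm-start f values onto the drawn windows by center
    f_by_center = {}
    for h, f in zip(histograms, full.window_free_energies):
        f_by_center.setdefault(round(h.center, 9), f)

    draws = np.empty((n_boot, full.pmf.z.size))
    for b in range(n_boot):
        drawn = []
        for c, g in groups.items():
            if len(g) == 1:
                drawn.append(_multinomial_resample(g[0], rng))
            else:
                drawn.append(g[rng.integers(len(g))])
        f0 = np.array([f_by_center[round(h.center, 9)] for h in drawn])
        sol = solve_wham(drawn, thermo, tol=tol, max_iter=max_iter, f_init=f0 - f0[0])
        prof = sol.pmf
        if reference_region is not None:
            prof = reference_pmf(prof, reference_region)
        else:
            mask = prof.defined
            prof = dc_replace(prof, W=prof.W - np.mean(prof.W[mask]))
        draws[b] = prof.W
    sigma = np.full(draws.shape[1], np.nan)
    ok = np.isfinite(draws).sum(axis=0) >= 2
    sigma[ok] = np.nanstd(draws[:, ok], axis=0, ddof=1)
    return sigma
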