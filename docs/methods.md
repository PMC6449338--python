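# Methods

## Scope and model

`permflux` implements the analysis chain that turns biased (umbrella)
sampling of a permeant along a membrane normal into a permeability, under
the inhomogeneous solubility-diffusion (ISD) model: a potential of mean
force W(z) from WHAM, a local diffusivity D(z) from the force-correlation
method, the local resistance R(z) = exp(W/RT)/D and its integral, whose
reciprocal is P. The ISD model assumes quasi-equilibrium solubility-
diffusion transport in one dimension with position-dependent D and no
memory; those assumptions are inherited, not tested, by this package.

Internal units are nm, ps and kJ/mol. Conversions (1 nm/ps = 10³ m/s,
1 nm²/ps = 10⁻⁶ m²/s, 1 ps/nm = 10⁻³ s/m) are applied exactly once, at
reporting boundaries.

## Synthetic generator: what it emulates, what it does not

The generator (`membrane1d`) replaces all-atom MD with the minimal process
whose exact permeability is the ISD integral: 1D overdamped Langevin
dynamics on a smooth parametric landscape, integrated by Euler–Maruyama in
the Itô convention with the mandatory D′(z) drift correction,

    dz = [−D(z)(W′(z) + k_u(z−z0))/RT + D′(z)] dt + √(2 D(z) dt) ξ.

Without the D′ term the stationary density would acquire a spurious 1/D
bias; a dedicated test verifies that a strongly varying D with W ≡ 0
still yields a flat stationary histogram.

The landscape is a central Gaussian barrier (plus optional symmetric
Gaussian interfacial wells) shifted so W(±half-width) = 0 exactly, and a
diffusivity that dips smoothly from a bulk value D_w to a core value D_m.
Presets mirror the reported PMF ladder for cisplatin in model membranes:
`dopc-like` (40 kJ/mol), `normal-0chl-like` (62 kJ/mol),
`normal-33chl-like` (70 kJ/mol). Diffusivities (D_w = 5×10⁻³, D_m =
1–2×10⁻³ nm²/ps) are plausible small-molecule values on the scale such
simulations report; they are declared constants of the study conditions,
not fits.

What the generator deliberately does **not** emulate: 3D membrane
structure, lipid degrees of freedom, anomalous/subdiffusive force memory,
slow bilayer relaxation, or finite-size/curvature effects. Passing
recovery tests therefore demonstrates correctness of the estimators under
ISD assumptions — not that those assumptions hold for any particular real
membrane.

Umbrella defaults follow the emulated protocol: spring constant
k_u = 1000 kJ/mol/nm², window spacing 0.1 nm, T = 320 K (RT ≈ 2.661
kJ/mol). The default timestep 0.01 ps keeps k_u·dt·D/RT ≈ 0.02 ≪ 1; a
guard rejects timesteps whose typical per-step displacement exceeds half
the barrier width. The equilibration/production split (20 000 / 200 000
steps by default) is a free parameter of the 1D process chosen to be many
window relaxation times (τ = RT/(k_u D) ≈ 0.5 ps); it has no MD-timescale
meaning.

Known integrator bias: Euler–Maruyama inflates the stationary variance of
a harmonic window by a factor 1/(1 − θ/2) with θ = k_eff·dt·D/RT (≈ +2% at
defaults) and shrinks the ACF decay time by the same order; the two biases
cancel to first order in the force-correlation D estimate. First-passage
estimates carry an O(√dt) discrete-crossing bias, small against the
statistical error at the particle counts used.

## WHAM

The self-consistent equations are iterated in probability space with the
bias Boltzmann factors precomputed (underflow to zero is harmless here),
gauge fixed by f₀ = 0, and convergence declared when max|Δf_i| ≤ 10⁻⁶
kJ/mol (default cap 10⁵ iterations; failure raises an error carrying the
residual). Bins with zero aggregate counts are NaN, never interpolated;
downstream integration fails loudly if such bins fall inside the
integration limits. The unbiased density is normalized to unit integral
before conversion to W — a pure gauge choice removed by referencing.

Choices where the emulated protocol is silent:

- **Bin width 0.02 nm** (5 bins per window spacing): resolves the window
  ladder without starving counts.
- **Per-replicate WHAM then averaging** (the reading of "average of all
  ligands"); a `pooled=True` flag solves one WHAM over all replicates.
- **Referencing**: W is shifted to zero mean over a declared bulk-water
  region; the pipeline default uses both slabs (±[2.0, 2.3] nm) of the
  symmetric synthetic landscapes. Idempotent by construction.
- **No symmetrization** of W about z = 0.
- **Bootstrap** (default 400 draws; scaled-down counts are used where a
  test only needs the sigma scale): each draw picks one complete
  histogram per window center from the replicates there — complete
  histograms are the independent data points. Centers with a single
  replicate fall back to multinomial count resampling behind an explicit
  consent flag, with a logged warning. Draws warm-start from the
  full-data fixed point.
- **Replicate averaging sigma**: σ² = s²_replicates + mean(σ_i²) — the
  across-replicate standard deviation (not the SEM, matching the
  convention of reporting block/ligand scatter directly) combined in
  quadrature with per-profile sigmas. The same rule is used for D(z).

An independent oracle test cross-checks the fixed point against direct
BFGS minimization of the WHAM negative log-likelihood on a small problem
(agreement to 10⁻⁴ kJ/mol).

## Diffusion from force correlations

ΔF is the recorded total systematic force (landscape + restraint) minus
its window mean; on a flat landscape the window is an exact
Ornstein–Uhlenbeck process with A = k_u·RT and τ = RT/(k_u·D), so
RT²/(Aτ) = D identically — the key unit-and-correctness anchor, asserted
to within sampling error in the tests. The ACF uses the biased 1/N
estimator (FFT-based). The exponential fit runs from lag 0 to the first
drop below A·e⁻³, with max lag capped at 10% of the window duration; the
ACF integral is taken analytically as A·τ, never numerically from the raw
ACF. Errors: four contiguous blocks, per-block estimates, their standard
deviation as the error and their mean as the value; blocks combine within
replicate first, then across replicates.

Finite blocks bias τ (hence D) by O(τ/T_block); tests size their
trajectories so blocks span hundreds of correlation times where D is
slowest. When only positions exist (pullx without pullf), the reader
reconstructs the restraint force −k_u(z−z0) as a documented fallback.

## Resistance, permeability, errors

D and σ_D are interpolated linearly onto the PMF grid (D varies slowly;
W drives r). Integration is trapezoidal over [z1, z2] = [−2.3, +2.3] nm
by default, with end nodes interpolated exactly at the limits; Simpson
was considered and rejected as spurious precision given histogram noise.
Error propagation is first-order with independent bins:

    σ_r = r·√[(σ_W/RT)² + (σ_D/D)²],  σ_R = √Σ(w_b σ_r,b)²,  σ_P = σ_R/R².

A covariance treatment between bins (WHAM correlates neighbouring bins)
is deliberately out of scope; the independence assumption is declared,
not derived. P·R_total = 1 holds exactly by construction.

## Kinetics and structural profiles

Uptake is fitted as C(t) = C_inf(1 − e^(−kt)) by unweighted least squares
(saturating form, since uptake plateaus; a free-offset variant is behind
a flag), and P = k·r/3 for a sphere with r = (3V/4π)^⅓ (2 pL → r ≈ 7.82
µm). Density profiles are frame-averaged histograms divided by bin
volume; head-group peaks are refined by 3-point parabolic interpolation;
membrane thickness vs cholesterol uses ordinary least squares with the
Pearson r reported; order parameters use the standard second-Legendre
form S = ⟨3cos²θ − 1⟩/2 without the −S_CD negation, taking precomputed
orientation cosines as input (whether the reference vectors are C–H or
C–C is the caller's choice).

## Problem sizes and determinism

Default validation sizes — 51 windows × 3 replicates, 2×10⁵ steps per
window, 50 bootstrap draws, 300 first-passage particles — were chosen so
the whole suite completes in about a minute while leaving every
statistical margin comfortable; they are package defaults, and all
stochastic paths are seeded (identical seeds give bit-identical output,
including inside the compiled kernels).

## Known limitations

- The estimators inherit every ISD assumption; none of the tests probe
  anomalous diffusion or memory effects.
- WHAM bin-to-bin covariance is ignored in σ_R (declared above).
- The XVG reader targets the plain two-column pull dialect only.
- Landscapes are smooth parametric forms; there is no support for fitting
  arbitrary tabulated W/D as ground truth (they can still be analysed via
  the profile containers directly).
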