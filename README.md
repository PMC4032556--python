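# md2bd — coarse-grained MD heat baths coupled to Brownian dynamics

`md2bd` simulates a heavy particle (a protein-sized sphere) immersed in a
gas of light point particles (a caricature of solvent) that interact with
it only through elastic collisions, and couples that molecular-dynamics
(MD) description to Brownian-dynamics (BD) models of the same particle so
that the expensive MD is run only where detail matters — for example next
to a membrane carrying receptors, while the bulk of the cell is handled by
the cheap overdamped model used in BD simulators such as Smoldyn.

It is aimed at people building or validating multiscale particle
simulations of intracellular processes: it provides the heat-bath models,
the exact boundary-injection samplers that make a finite simulation box
statistically identical to an infinite bath, the interface corrections
that let a particle straddle the MD/BD boundary without bias, and a
worked application with a PDE reference solution.

## The models

**Heat baths.** A heavy particle of mass `M` collides elastically with
point particles of mass `m` (mass ratio `mu = M/m`).  Three baths are
provided:

* **A** — one-dimensional, Maxwellian bath velocities;
* **B** — three-dimensional, heavy sphere of radius `R`, Maxwellian bath;
* **C** — three-dimensional, bath particles with a single fixed speed and
  isotropic directions.

For prescribed friction `gamma` and diffusion constant `D`, the bath's
Poisson density `lambda_mu` and velocity scale `sigma_mu` are chosen so
that as `mu -> infinity` the heavy particle converges to the Langevin
dynamics

    dX = V dt,      dV = -gamma V dt + gamma sqrt(2 D) dW,

whose overdamped (`gamma -> infinity`) limit is `dX = sqrt(2 D) dW`.
Model A, for example, uses `lambda_mu = (1/4) sqrt(pi (mu+1) gamma/(2D))`
and `sigma_mu = sqrt((mu+1) D gamma)`.

**Boundary injection.** Bath particles that would enter the simulated
domain during a step of length `dt` arrive at rate `gamma (mu+1) dt / 8`
per 1-D boundary (`3 gamma (mu+1) dt / (16 pi R^2)` per unit area in
3-D), with penetration depth distributed like `erfc(d / (sigma_mu dt
sqrt(2)))` and a matching one-sided truncated Maxwellian velocity.  The
erfc distribution is sampled by an acceptance–rejection scheme with an
exponential envelope; the optimal envelope constants are `a1 = 0.532`,
`a2 = 0.814`, accepting 86% of proposals.

**MD/BD coupling.** When the heavy particle straddles the interface
between the MD subdomain and the BD subdomain, the collisions it would
have received from the unsimulated side are replaced by a per-step
velocity correction `alpha dt + beta sqrt(dt) xi`.  In 1-D `alpha` and
`beta` are exact integrals over the half-line bath; in 3-D they are
closed-form surface integrals over the exposed spherical cap that
interpolate continuously between zero (fully in MD) and the full Langevin
coefficients (fully in BD).

**Application.** Protein binding to a reactive membrane: MD model B next
to the membrane (with a moving window of explicitly simulated solvent),
velocity Langevin dynamics in an overlap buffer, overdamped BD in the
bulk, and per-contact binding probability `P = K sqrt(2 pi/(D gamma))`.
The mean-field reference is the 1-D diffusion equation with a Robin
boundary `D rho_x = K rho`, solved by Crank–Nicolson.

## Worked example

```python
import numpy as np, md2bd

# 1-D hybrid: MD model A in (-L, 0), Langevin BD in (0, L)
ens = md2bd.run_hybrid_1d(mu=100, gamma=10, D=1, L=10, R=1,
                          dt=1e-4, t_end=1.0, n_realizations=2000,
                          seed=4, save_every=1000)
t, msd, se = md2bd.estimate_msd(ens)
print(f"MSD(t=1)  = {msd[-1]:.3f} +- {se[-1]:.3f}")
print(f"reference = {md2bd.msd_langevin(1.0, D=1, gamma=10):.3f}")

from scipy import stats
sd = np.sqrt(2 * 1.0 * (1.0 - md2bd.t_star(10.0)))
ks = stats.kstest(ens.X[:, -1, 0], stats.norm(scale=sd).cdf)
print(f"KS p-value at t=1: {ks.pvalue:.2f}")
```

Output:

```
MSD(t=1)  = 1.657 +- 0.051
reference = 1.700
KS p-value at t=1: 0.93
```

The ensemble mean squared displacement of the hybrid run matches the
Langevin closed form `2Dt - 3D/g + 4D e^{-gt}/g - D e^{-2gt}/g` within
one standard error, and the position law at `t = 1` is indistinguishable
from the shifted Gaussian with variance `2D(t - 3/(2 gamma))` — i.e. the
particle cannot "feel" where the MD region ends and the BD region begins.

A command-line umbrella is installed as `md2bd` with subcommands
`run-a`, `run-3d`, `run-hybrid-1d`, `run-hybrid-3d`, `run-binding`,
`sample-erfc`, `optimize-envelope` and `pde`; each takes a JSON config
and writes CSV trajectories (`md2bd run-a --config cfg.json --out traj.csv`).

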