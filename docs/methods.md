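# Methods

This note records the models implemented in `md2bd`, their assumptions,
the numerical choices made where the construction was genuinely open, and
what the desk-scale validation runs do and do not demonstrate.

## Heat-bath models and their limits

All quantities are dimensionless.  A heavy particle (mass `M`, radius
`R`) sits in an ideal gas of light point particles (mass `m`,
`mu = M/m`); the only interaction is the frictionless elastic collision,
so post-collision velocities follow from conservation of momentum and
energy alone.  The bath is a spatial Poisson field with density
`lambda_mu` and a prescribed velocity law with scale `sigma_mu`:

| model | dim | velocity law | `lambda_mu` | `sigma_mu` |
|---|---|---|---|---|
| A | 1 | Maxwellian | `(1/4) sqrt(pi (mu+1) g / (2D))` | `sqrt((mu+1) D g)` |
| B | 3 | Maxwellian | `(3/(8R^2)) sqrt((mu+1) g / (2 pi D))` | `sqrt((mu+1) D g)` |
| C | 3 | fixed speed, isotropic | `(3/(8 pi R^2)) sqrt((mu+1) g / D)` | `2 sqrt((mu+1) D g)` |

(`g` = `gamma`.)  These closed forms were fixed by requiring two
independent identities to hold, and both are enforced by tests: (i) the
free-flight boundary-crossing count equals `g(mu+1)dt/8` in 1-D and
`3g(mu+1)dt/(16 pi R^2)` per unit area in 3-D; (ii) the heavy particle's
velocity-increment statistics in a full bath give drag slope `-g` and
per-component variance rate `2 g^2 D` (fluctuation–dissipation), so the
`mu -> infinity` limit is the Langevin dynamics with the prescribed
`(g, D)`.  A consequence worth noting: the heavy particle's stationary
velocity variance is `sigma_mu^2/(mu+1) = D g` exactly under the limit
law, while strict equipartition against the bath gives `D g (mu+1)/mu`;
at the validation scale `mu = 100` this is a 1% effect, far inside the
statistical resolution of every test.

## Engines

**1-D (model A).**  Within a step: free flight, chronological resolution
of heavy–bath collisions at exact crossing times, removal of particles
that left the domain, then a Bernoulli influx per boundary.  Equal-mass
bath–bath collisions exchange velocities, which is precisely a relabeling
of free-flight trajectories; since no observable (heavy-particle
dynamics, the unordered set of bath phase-space points, boundary fluxes)
depends on particle labels, the engine skips the relabeling sort
entirely.  The heavy particle is treated as a point in the full model-A
engine (the radius has no effect on 1-D dynamics); the hybrid engine
gives it faces at `X +- R` because the interface bookkeeping needs them.

**3-D (models B, C).**  Sphere–point collision times are the exact roots
of the per-particle quadratic, processed chronologically with an event
cap; grazing (double-root) contacts count as misses.  The bath lives in
an axis-aligned window with Poisson-number influx per face (mean = flux
law x face area), which reduces to the single-insertion Bernoulli rule
when the mean is small but stays valid for large faces.  Faces not
perpendicular to a coupling interface reuse the same entrant law rotated
to the face normal; this relies on the isotropy of both velocity laws.
Entrant sampling is exact: model B uses the erfc depth profile with a
matching one-sided truncated Maxwellian normal speed; model C inverts the
triangular depth CDF `d = sigma dt (1 - sqrt(1-u))` and draws the normal
speed uniformly on `(d/dt, sigma]`, the conditional law on the shell.
Insertions that would fall inside the heavy sphere are discarded
(thinning), matching the equilibrium field conditioned on no overlap.

**Moving window.**  When the sphere comes within `R + 0.5` of a lateral
window face the window is re-centred in one jump and the newly exposed
volume is filled from the unconditioned equilibrium field.  That field is
the exact marginal law of the bath that was not being simulated there, so
the seam is statistically invisible; a stationarity test confirms a flat
density profile across it.

**Samplers.**  The erfc distribution (`sqrt(pi) erfc(z)`, the normalised
penetration-depth law) is sampled by acceptance–rejection from an
exponential proposal `z = -a1 log U`, accepting when
`U U' < a2 erfc(z)`; the envelope constants `a1 = 0.532`, `a2 = 0.814`
maximise the total acceptance `a2/(a1 sqrt(pi)) = 0.863` subject to
`a2 erfc(z) e^{z/a1} <= 1`, and the optimiser that recomputes them works
on the numerically stable `log erfcx(z) - z^2 + z/a1` form.  One-sided
truncated Gaussians use exact rejection: naive for cutoffs below
`0.3 sigma`, the translated-exponential (Robert, 1995) proposal in the
tail; both are exact, so no truncation bias enters the influx laws.

## MD/BD coupling

While the heavy particle straddles the interface (`X1` within `R` of it),
each step adds `alpha dt + beta sqrt(dt) xi` to the post-collision
velocity, evaluated at the pre-step state (Ito convention).  The 1-D
one-sided coefficients are the exact erfc-form integrals; their Taylor
forms are implemented only as cross-checks and never used in stepping.
The 3-D closed forms interpolate between `0` at `X1 = -R` and the full
Langevin drift `-gamma V` / noise `gamma sqrt(2D) I` at `X1 = R`; the
noise matrix is diagonal and evaluated at `V = 0` (its leading `V`
dependence is dropped, an `O(V/sigma_mu)` approximation).  Two
independent oracles pin these forms down in the tests: numerical surface
quadrature over the exposed spherical cap with velocity moments obtained
by 1-D quadrature (agreement to relative 1e-4), and brute-force one-sided
collision Monte Carlo (agreement within 3 SE).

Influx through the interface face is suppressed exactly where the sphere
blocks it: in 1-D the whole insertion is skipped while straddling; in
3-D inserted positions overlapping the sphere are discarded, since the
cap correction already accounts for collisions on the BD-side surface.

## Receptor-binding application

Geometry (defaults): membrane at `x1 = 0`; MD layer `[0, h]` with
`h = 4`; Langevin region up to `h3 = 12`; overdamped region from
`h2 = 8` (the two BD levels overlap on `[h2, h3]`); domain length
`L1 = 100`; lateral window half-width `h4 = 3`; `R = 1`, `D = 10`,
`gamma = 100`, `K = 1`, so the per-contact binding probability is
`P = K sqrt(2 pi/(D gamma)) = 0.0793`.

Choices the construction leaves open, and what was done:

* **Time bookkeeping.**  The velocity-Langevin model lags the overdamped
  one by `t* = 3/(2 gamma)` at large times, so `t*` is subtracted from
  the clock on switching into the Langevin level and added back on
  leaving it.  Velocities at a switch are drawn from the stationary
  Maxwellian (per-component variance `D gamma`).  With Maxwellian
  initialisation the asymptotic lag is strictly `1/gamma`; retaining the
  `3/(2 gamma)` shift is a deliberate simplification whose error,
  `1/(2 gamma) = 0.005` per switch, is far below the statistical
  resolution of the validation runs.
* **Bath lifecycle.**  The explicit bath exists only while the protein's
  centre is below `h + R + 0.5` (dropped again above `h + R + 1.0`,
  hysteresis to avoid churn).  While the protein is outside that buffer
  the sphere cannot touch any bath particle, and the unobserved bath is
  exactly the unconditioned equilibrium field, so creating it fresh on
  entry is unbiased, not an approximation.
* **Membrane.**  The membrane reflects bath particles specularly (the
  image of the removal-plus-influx construction, preserving the
  equilibrium field) and the protein binds with probability `P` at
  contact (`X1 = R`), else its normal velocity is reflected; contact
  detection is exact within the event loop.
* **Coordinates.**  The particle model simulates the sphere centre on
  `[R, L1]`; the PDE reference is solved on the matching contact
  coordinate `x in [0, L1 - R]` with Robin condition `D rho_x = K rho`
  at `x = 0` and no-flux at the far end, from a uniform initial
  condition.  Initial centre positions are uniform on `[R, L1]`.
* **Lateral directions.**  The `x1`-marginal and the binding statistics
  are exactly independent of how `x2, x3` are bounded, so the protein
  moves laterally unbounded and the moving window supplies solvent
  wherever it goes; no lateral walls are imposed.

The PDE is solved by Crank–Nicolson with second-order Robin/Neumann
ghost-node boundaries; the discrete scheme conserves interior-plus-
absorbed mass to solver precision (the absorbed mass is accumulated as
`K dt (rho_0^n + rho_0^{n+1})/2`, which telescopes exactly against the
scheme), and a three-level refinement study observes order >= 1.9.

## Validation scale and what it shows

The stochastic ensemble checks run at a reduced mass ratio `mu = 100`
with time steps `1e-5` (1-D MD), `1e-4` (hybrids) and `1e-5 / 1e-3`
(binding MD/overdamped), chosen so that per-step collision and influx
probabilities stay below 0.1 and the whole suite runs on a single CPU in
well under half an hour: model A with 200 realizations, the hybrids with
10^4, the binding application with 10^3.  At `mu = 100` the finite-mass
corrections are O(1%) — inside every statistical band used — with one
visible exception: at times shorter than a few mean collision times
(`gamma t` below ~0.3) the MD mean squared displacement sits measurably
below the Langevin curve because the heavy particle's velocity changes
in discrete collisions; ensemble comparisons therefore start at
`t = 0.05`.  Passing these tests shows the construction is unbiased at
the resolution of the ensembles used; it does not probe the `mu -> 
infinity` convergence rate, hydrodynamic memory (absent from ideal-gas
baths by construction), bath–bath interactions in 3-D (none), or
many-protein effects (one heavy particle throughout).

Other numerical guards: an iteration cap (10^4) on the within-step
collision cascade turns pathological configurations into a step-size
error instead of a hang; grazing contacts and exactly-touching
separating pairs are classified as non-events; trajectory CSVs are
written at 17 significant digits and read back with round-trip float
parsing, so equal seeds give bit-identical files.

## Known limitations

* The noise matrix of the 3-D correction is `V`-independent by
  construction; for heavy-particle speeds approaching `sigma_mu` the
  correction's drift is exact in 1-D but only linear-in-`V` in 3-D.
  This is not free: the omitted drift contribution is negative-definite
  in `V` (it always points toward the MD side), of relative size
  `lambda_mu pi R^2 D gamma / ((mu+1) |alpha_1(0)|)` — about 1% at
  `mu = 100`, decaying like `1/sqrt(mu+1)`.  At `mu = 100` it produces a
  measurable rightward shift of the heavy particle's `X1` law (mean
  `~ +0.02` by `t = 1`), which a Kolmogorov–Smirnov test with 10^4
  realizations resolves even though the MSD agrees within 3 SE; a
  control run of the full 3-D MD with no interface shows no such shift,
  and the shift is unchanged under halving of the time step, pinning it
  on the linearization rather than the engine or discretization.  The
  1-D coupling, which uses the exact `V`-dependent one-sided
  coefficients, shows no bias at the same scale.  At mass ratios of
  10^3 and above the effect is an order of magnitude smaller and
  statistically invisible at any ensemble size used here.
* The hybrid engines assume the heavy particle stays away from the outer
  MD boundary (a guard band warns otherwise); heavy-particle behaviour
  at the outer wall is not part of the model.
* `mu` must be large for the BD coupling to be meaningful; the engines
  run at any `mu > 0` but the corrections embed `mu -> infinity`
  expansions of the collision statistics only through their exact
  `lambda_mu`, `sigma_mu` dependence.
* The binding application models a single protein; receptor saturation
  and inter-protein interactions are out of scope.
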