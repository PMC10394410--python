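# Methods

## Model

Transcribing RNA polymerase II is modelled as a driven lattice gas: particles
on a 1-D chain of `N` sites (the gene body, one site per coverage bin) hop
forward with site-dependent rate `p_i` and backward with rate `q_i = b p_i`,
subject to the exclusion rule (a hop succeeds only into an empty site).
Particles are injected at the left boundary (initiation) and leave through
the right boundary (termination).  Genomic regions where polymerase pauses
correspond to local minima of the rate profile.

Two forward backends implement the expected-occupancy dynamics:

* **Lattice mean-field** (`polrate.lattice`).  Closing the occupancy moment
  hierarchy by factorising neighbour correlations gives `N` coupled ODEs,

      dphi_i/dt = p_{i-1} phi_{i-1}(1-phi_i) - p_i phi_i(1-phi_{i+1})
                + q_{i+1} phi_{i+1}(1-phi_i) - q_i phi_i(1-phi_{i-1}),

  with boundary sites exchanging particles with reservoirs at the injection
  rates `p0`, `q_{N+1}` and exit rates `q_1`, `p_N`.  Integrated with an
  adaptive explicit Runge–Kutta method (scipy, default `atol = rtol = 1e-8`);
  the system is non-stiff for the rate magnitudes in scope.  An exact
  event-driven (Gillespie) simulator of the underlying stochastic process
  quantifies the factorisation error; on small lattices at low injection the
  stationary mean-field occupancies agree with exact master-equation
  enumeration to within 10% relative error.

* **Hydrodynamic limit** (`polrate.hydro`).  Under Euler scaling
  (`a -> 0`, `N -> infinity`, `L = N a` fixed) the density `rho(x, t)` obeys
  the conservation law

      d(rho)/dt = -d/dx [ lambda(x) rho(1-rho) - nu(x) d(rho)/dx ],
      lambda = p~ (1-b),   nu = (a/2) p~ (1+b),

  with `p~(x) = a p_i` the continuum rate profile.  The solver is a
  conservative finite-volume method of lines whose interface fluxes use the
  discrete two-point product form `p~ rho_L (1 - rho_R) - q~ rho_R (1 -
  rho_L)`; its Taylor expansion reproduces the advection–diffusion flux
  above, and at `a = 1` the semi-discretisation is *identical* to the lattice
  mean-field system, which therefore serves as an independently coded oracle
  (agreement to ~1e-10 at matched tolerances; the acceptance suite asserts
  1e-6).

Boundary conditions are ghost-cell reservoirs.  `fixed-density` couples the
end cell to a reservoir at density `r` (influx `p~ r (1-rho)`, blocked exit
`p~ rho (1-r)`), used to relax to the non-equilibrium stationary state
(NESS).  `zero-influx` removes the incoming interface flux and keeps the free
outgoing one — the continuum analogue of initiation blocked by triptolide,
with elongation and termination unaffected.  The NESS is found by
long-horizon time stepping with stationarity detection (`max |d rho/dt|`
below tolerance, default `1e-8` per unit time, at three consecutive
checkpoints) rather than a nonlinear root solve: bottlenecked profiles create
slowly relaxing shock-like fronts that Newton methods handle poorly.  At
stationarity the interface flux is constant in `x` by telescoping, which the
tests check to 1e-6 relative (using a tighter relaxation tolerance of 1e-10,
since a residual of `eps` per unit time permits a cumulative flux drift of
`N a eps` across the lattice).

Time stepping is explicit Runge–Kutta (Heun or classical RK4) at a fixed step
guarded by `dt = c * a / (2 p~_max (1+b))` with `c = 0.5` by default; the
advective CFL number `max(lambda) dt / a` then stays at 0.25, comfortably
inside the stability region, and the positivity of the product-form flux
keeps densities in [0, 1] (asserted, with a 1e-9 round-off clamp, on every
returned field).

## Prior and likelihood

The rate profile is positive, bounded and smooth by construction:
`p~ = p~max * sigmoid(f)` with a latent Gaussian process
`f ~ GP(m, sigma_f^2 exp(-(x-x')^2 / 2 l^2))` evaluated on the solver grid
(dense Cholesky with an adaptive diagonal jitter from `1e-10 sigma_f^2`
doubling to at most `1e-6 sigma_f^2`; no inducing points — at 20-nt binning a
gene is a few thousand sites at most).

Observations are read-scale profiles `y_ij` at positions `x_i` and run-on
times `t_j` after treatment, plus the pre-treatment profile `y*`.  Read
counts are proportional to occupancy with unknown inverse amplification
`kappa` and additive Gaussian noise on the density scale:

    kappa y_ij = rho(x_i, t_j; f) + eps,   eps ~ N(0, sigma_eps),

so the log-likelihood is the Gaussian density of the residuals
`kappa y_ij - rho(x_i, t_j)`, normalised over all `n * t` observations.
`rho` is computed by integrating the transport equation from
`rho(x, 0) = kappa y*(x)` (clipped into [0, 1]) with zero-influx boundaries;
a failed forward solve maps to log-likelihood `-inf` (state rejected) so
slice-sampling brackets remain well defined.

The five hierarchical parameters `theta = (m, sigma_eps, kappa, sigma_f, l)`
carry a scaled-sigmoid Gaussian prior `theta = theta_min + (theta_max -
theta_min) sigmoid(xi)`, `xi ~ N(mu_xi, sigma_xi^2)`.  `sigma_xi` is read as
a standard deviation; at the only setting used, `(0, 1)`, the
std-versus-precision reading is immaterial.  For real data, `kappa` bounds
are derived from the total count `Y` via `kappa = P / Y` with `P`, the number
of template-bound polymerases per cell, taken between 11e5 and 18e5, and the
rate cap defaults to 6e3 nt/min (a deliberately safe multiple of measured
elongation speeds); both are configurable.

## Sampler

The posterior over `(f, theta)` is explored by block Gibbs with elliptical
slice sampling (ESS), which is rejection-free and tuning-free for targets
with Gaussian priors.  Each sweep performs:

1. ESS on the whitened latent `eta` (`f = m + chol(K) eta`), against the
   data likelihood;
2. ESS on the whitened hyper vector `z` (`xi = mu_xi + sigma_xi z`), with
   `f` reconstructed as `m' + chol(K') eta` — valid under kernel changes
   because the N(0, I) prior on `(eta, z)` is exact in these coordinates;
3. interweaved centred updates with `f` held fixed: `(m, sigma_f, l)`
   against the GP density of `f` alone (the likelihood is flat in them given
   `f`, so this block needs no forward solves), then `(sigma_eps, kappa)`
   against the data; afterwards `eta` is re-whitened under the new kernel.

Step 3 exists because the whitened parameterisation alone mixes the kernel
hyperparameters arbitrarily slowly once the data pin the latent field: any
move of `(sigma_f, l)` at fixed `eta` drags `f` and must preserve a tight
fit.  Centred and non-centred updates are both exact conditional updates of
the same joint posterior, and interweaving them (in the spirit of
ancillarity–sufficiency interweaving) combines their complementary mixing
regimes.  The chain starts deterministically at the prior-box midpoints with
a flat latent field.

The sampler's log target in whitened coordinates equals the joint density of
`(f, xi)` up to the Jacobian `log|det chol(K)| + 5 log sigma_xi` of the fixed
linear maps (property-tested).  ESS itself is validated against a flat
likelihood (prior recovery) and a 1-D conjugate Gaussian case (closed-form
posterior).

Defaults are 10^4 sweeps with 2x10^3 burn-in.  Summaries are equal-tailed
linear-interpolation quantiles: medians with 99% intervals for the rate
profile and 95% intervals for hyperparameters.  Posterior predictives
propagate evenly thinned kept draws through the forward model and add
`N(0, sigma_eps)` observation noise.

## Synthetic benchmark

`polrate.simulate.generate_study` regenerates the reference simulation
study: a lattice of `L = 100` sites (`a = 1`, `b = 0`), rate profile drawn
from the GP with `(m, sigma_f, l, p~max) = (0.29, 0.67, 7.32, 3)`, NESS with
both reservoirs at density 0.5, depletion observed at `t = (30, 60, 300)`
minutes, true `kappa = 1` (inside the (0.8, 1.2) prior box) and, by default,
no added observation noise (profiles are extracted exactly, matching the
near-perfect overlay the benchmark is known for).  Typical draws produce a
deep interior rate minimum acting as a bottleneck that separates a
high-density upstream phase from a low-density downstream phase; after
influx is blocked, a reverse wavefront empties the upstream region.

Two deliberate numerical-asymmetry choices matter for noise-free data:

* The generator integrates with RK4 at `dt = 0.02`, finer than the
  likelihood's default solver (Heun at the CFL step).  Ground truth should
  not depend on the inference-time solver setting, and the resulting
  truncation-level residual floor (~1e-5 rms) gives the noise scale
  `sigma_eps` a well-defined, tiny posterior instead of an improper collapse
  toward zero — with exactly self-consistent data the likelihood grows
  without bound as `sigma_eps -> 0` and the chain freezes.
* The generator shares the kernel/Cholesky path with the prior module, so
  there is no train/test skew in the GP draw.

What the generator does *not* emulate about real ChIP-seq: count noise
(Poisson/negative-binomial rather than additive Gaussian), the 150–300 nt
fragment-size blur, cross-cell heterogeneity, mappability artefacts, and
poised (non-engaged) polymerase upstream of the TSS.  Passing the synthetic
benchmark therefore demonstrates correctness of the solver–prior–sampler
pipeline under the stated observation model, not robustness to those
real-data effects.

## Numerical choices and sizes

* Likelihood solver: Heun, `dt ~ 0.083` for `p~max = 3` (~1 ms per solve on
  a 100-site lattice); a full 10^4-sweep chain is ~10–15 min on one core.
  Temporal truncation error (~1e-5 rms against a fine fourth-order
  reference) is far below the noise scale of any realistically noisy data
  set; for oracle-grade accuracy use RK4 with `dt <= 0.01`.  A coarser step
  (`cfl = 0.8`) is stable but its ~1e-3 error approaches the fitted noise
  scale of noise-free benchmarks, so it is not the default.
* Test-suite fits use shortened chains (1200 sweeps, 500 burn-in) on the
  same `L = 100` problem — the package's standard smoke configuration; the
  acceptance script runs the full 10^4-sweep settings.
* Quantile convention: `numpy` linear interpolation; documented through the
  1..100 worked example in the tests.
* Degenerate inputs: empty lattices, saturated densities (`rho` 0 or 1),
  zero rate profiles and single-time grids are all exact no-ops and are
  covered by tests; `theta` exactly on a prior bound is rejected by the
  inverse sigmoid transform (domain error) rather than mapped to infinity.

## Known limitations

* The mean-field/hydrodynamic closure ignores neighbour correlations; on
  small stochastic systems the documented error is up to ~10%.  Inference
  quality on real data inherits this model error.
* `b` (backward-hop strength), `a`, and the boundary densities are
  configuration, not inferred.
* With noise-free, solver-consistent data the noise scale is identified
  only by the truncation floor; posterior `sigma_eps` then measures solver
  mismatch, not biology.
* Kernel hyperparameters are weakly identified from density profiles alone
  (smoothed-out rate wiggles leave no imprint); their posteriors lean on the
  prior box, and moderate miscalibration of `(l, sigma_f)` intervals is
  expected.
* Convergence is slow on noise-free data: the latent field must anneal from
  a flat start onto a tight data manifold while `sigma_eps` co-adapts.
  Shortened chains (around 10^3 sweeps) are reliable for pause localisation
  and the rate profile's gross shape but systematically under-disperse — and
  can mis-centre — the kernel-hyperparameter posteriors; credible intervals
  for `(l, sigma_f)` should be trusted only from full-length (10^4-sweep)
  chains, and a small persistent misfit (a few `sigma_eps`, typically at the
  outflow boundary) can survive even those.
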