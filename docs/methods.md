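# Methods

## Generative model

The study region is the square D = [−5, 5]² carrying a single environmental
variable; by default x(z) = z₁, a linear west–east gradient, so the habitat
measure μ_x (geographic area per unit of environmental value) is uniform
with density 10 on Im(x) = [−5, 5]. Species individuals follow an
inhomogeneous Poisson process with intensity λ∘x; only the normalized
environmental density f = λ/∫λ is identifiable here, because all samples
are drawn conditionally on a fixed size (below), which removes the
intensity scale. f is Gaussian with optimum μ₀ and breadth σ₀, renormalized
on Im(x) — the generative sampler only produces points in D, so truncated
densities are the effective ground truth.

Reported presences are the effort-thinned process IPP(s·λ∘x), with
s: D → [0, 1] the probability of reporting an individual. Five effort
shapes are built in, all functions of z₁ alone (so the observation density
s_x equals the normalized effort profile): constant (CST); linearly
decreasing 1/10 − z₁/50 (LIN); an indicator of the western half scaled to
1/5 (CUT); a profile ∝ log(1+(z₁+1)²) with a zero at z₁ = −1 (HOL); and a
standard-normal profile (GS). The profiles are kept at their natural scale
(all within [0, 1]); the fixed-size sampling makes any positive rescaling
irrelevant.

Target-group (TG) occurrences pool the reported presences of many species
sampled by the same observers; only their *cumulated* density a enters the
theory, so a is modeled directly as a centered Gaussian with sd 20 (FLAT,
within 3.2% of uniform on the support), 2 (THICK) or 1 (THIN), never as
individual TG species.

### Default study conditions

| parameter | default | meaning |
|---|---|---|
| μ₀ | {−1, −4} | niche optimum: typical vs marginal (env. units) |
| σ₀ | {0.6, 1.5} | niche breadth: specialist vs generalist (env. units) |
| effort | CST/LIN/CUT/HOL/GS | observation-density shape |
| TG sd | 20/2/1 | FLAT/THICK/THIN group concentration |
| n | 20000 | occurrences and background points per fit |
| grid | 2001 nodes | environmental discretization of [−5, 5] |

## Simulation

All point sets are produced by rejection sampling: proposals uniform on D,
accepted with probability density/B, where B is 1.1 × the density maximum
over a 201×201 lattice (exact for the smooth or piecewise-constant
densities used; the safety factor covers the lattice gap). Sampling is
conditional on reaching exactly n accepted points, mirroring the fixed-size
design; one seeded generator is used per draw and recorded in the sample
metadata, so samples are byte-reproducible. The sampler aborts with the
observed acceptance rate if a density is so concentrated that the proposal
budget (5×10⁷ by default) would be exceeded.

## Fitting

The Poisson-process likelihood is approximated by down-weighted Poisson
regression: each background point carries quadrature weight |D|/n_b (their
sum is exactly the domain area), each presence the vanishing weight
ε·|D|/n_b with ε = 10⁻⁶ and response 1/weight. Halving ε moves the
estimates by < 10⁻³ (tested). Covariates are fixed to [1, w, w²] — the
log-Gaussian niche family — with no regularization. The weighted Poisson
ML problem is solved by damped Newton iteration on centered/scaled
covariates (relative log-likelihood tolerance 10⁻¹⁰, 100-iteration cap,
step halving on non-finite or decreasing steps), and the coefficients are
back-transformed exactly; statsmodels' GLM serves as an independent
cross-check in the tests, not as the implementation. A back-transformed
coefficient above 50 in magnitude marks divergence; β₂ ≥ 0 marks a
non-concave fit (no Gaussian niche — the signature of the expulsion
regime). Background points are deliberately *never* importance-reweighted
by the density they were drawn from: that modeling choice is the object of
study, and it is what makes the TG background target f/a rather than f.

## Theory targets and oracle

The expected estimate of each scheme is the argmin over the Gaussian family
of the KL divergence from its target density (f·s_x for UB, f/a for TGOB, f
for SEB), weighted by μ_x. Since both arguments are probability densities
on the same axis, the base measure cancels inside the log-ratio; under the
default uniform μ_x the divergence is computed as the plain trapezoid
integral of p·log(p/q). The argmin is computed by truncated moment
matching — on a fixed support the truncated Gaussians form a full
exponential family with sufficient statistics (w, w²), so the KL argmin is
the member whose truncated mean and variance equal the target's — with a
Nelder–Mead minimization of the discretized divergence as fallback. When
both inputs are Gaussian the product/quotient closed forms are attached:
precision addition for f·s_x, precision subtraction for f/a, with the
quotient flagged non-integrable when the niche is broader than the TG
density.

EXPULSION is flagged when the Gaussian quotient is non-integrable or when
more than 20% of the target's mass lies in the outer 5% of the support;
the raw edge-mass fraction is reported so users can re-threshold. This is
an operational definition of a qualitative regime; near the threshold
(e.g. the marginal generalist against the THICK group, edge mass ≈ 0.22)
the binary flag should be read together with the edge mass itself.

Derivatives for the bias diagnostics use central differences with a
smaller-magnitude one-sided (minmod) rule at jump discontinuities, which
keeps the CUT effort's jump from contaminating the variation measure. The
environmental grid uses 2001 equally spaced nodes and trapezoid-rule
integrals throughout; this resolves the narrowest density in the design
(sd 0.6) to below 10⁻⁴ integration error. Monte-Carlo estimation of μ_x
and of s_x for non-separable fields/efforts uses 10⁶ uniform points with a
recorded seed; values landing exactly on a bin edge go to the left bin.

## Verification design

The package's tests verify the displaced-target theory by comparing fitted
parameters to the KL-argmin oracle. The comparison tolerance (±0.1 on both
parameters) demands that Monte-Carlo error be well below it, and the
schemes differ sharply in how fast their estimates converge:

* UB fits converge quickly (background covers the whole support);
  n = 2×10⁵ keeps the standard error of μ̂ below ~0.02 in every cell.
* SEB and TGOB under the concentrated GS effort converge slowly for
  marginal species: the background carries almost no points where the
  niche lives, so the quadratic fit extrapolates. At the study size
  n = 20000 the SEB estimate for (μ₀ = −4, GS) shows a finite-sample
  deviation near +0.1 with SD(μ̂) up to 0.4. These cells are verified at
  n = 10⁶–2×10⁶; the hardest cell (TGOB, THICK group, GS effort,
  μ₀ = −4, σ₀ = 0.6) keeps SD(μ̂) ≈ 0.1 even at n = 4×10⁶ and is verified
  as a 12-replicate mean at n = 2×10⁶. Sizes were fixed from pilot
  standard-deviation measurements so that the verification SE sits below a
  third of the tolerance.

Study-condition results (the scenario grid, the acceptance script, the
examples) always use the default n = 20000.

## What the simulations do and do not show

The generator reproduces the idealized setting of the theory: a
one-dimensional environmental gradient, Gaussian niches, deterministic
environment, spatially independent (Poisson) individuals, and a detection
probability constant across species and space. Real presence-only data add
spatial clustering, raster (discrete) environments, multi-variable niches,
species-varying detectability and imperfect geolocation — none of which is
modeled, so passing tests validate the bias mechanisms and the estimator
algebra, not the magnitude of bias in any particular real dataset. The
site-aggregated variant of the target-group method, effort covariates, and
integrated/occupancy models are out of scope. Standard errors and
confidence intervals are not produced: the object of study is bias, not
variance.

## Design choices worth knowing

* The TG background re-uses the pooled TG occurrence sampler; a TG sample
  can also be re-tagged as background directly. The focal species is not
  included in the TG by default (including it would partially shield
  against expulsion); pooled TG backgrounds are always drawn at the full
  background size regardless of group composition.
* Per-scenario seeds derive from a master seed by a fixed affine counter
  scheme (`scenario_seed`), so any grid cell can be reproduced in
  isolation.
* `fit` accepts arbitrary point CSVs (`z1,z2,env,role`), so user-supplied
  point sets can be fitted; no GIS layer support is provided.
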