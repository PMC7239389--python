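# nichebias

Estimation bias of background-point schemes in presence-only species
distribution models (SDMs), studied by simulation against closed-form
theory.

## The problem

Presence-only SDMs estimate a species' environmental density *f* (its niche
response curve) from reported occurrences plus a set of *background points*
that stand in for the normalizing integral of the Poisson-process
likelihood. Opportunistic occurrence data — citizen-science records in
particular — are thinned by a heterogeneous *sampling effort* s(z): the
probability that an individual at location z gets reported. Background
points are supposed to mirror that effort across environments; when they do
not, the fit is biased in ways this package makes precise, simulates, and
checks against theory.

The model: individuals of a species follow an inhomogeneous Poisson point
process on a bounded region D with intensity λ∘x, where x(z) is an
environmental variable. Reported presences are the s-thinned process,
IPP(s·λ∘x), so along the environmental axis the observed density is
proportional to f·s_x, where s_x(w) — the *observation density* — is the
effort averaged over all locations with environment w, normalized over
Im(x). Three background schemes are compared, each characterized by the
density its estimate converges to (the KL-divergence argmin within the
fitted Gaussian family, weighted by the habitat measure μ_x):

| scheme | background points | asymptotic target |
|---|---|---|
| UB   | uniform on D                          | f·s_x |
| TGOB | pooled occurrences of a target group  | f/a (a = cumulated TG density) |
| SEB  | drawn from the effort density         | f (unbiased) |

UB therefore drags the estimated optimum toward where observers looked and
over-estimates specialization under concentrated effort; TGOB is immune to
the effort but biased by the target group's own ecology — a concentrated
TG density *expels* the estimated niche from its environmental range; SEB
is unbiased but requires knowing the effort.

The fit itself is the standard Berman–Turner device: a down-weighted
Poisson regression over presences and background points with log-quadratic
predictor β₀+β₁w+β₂w², inverted to the niche optimum μ̂ = −β₁/(2β₂) and
breadth σ̂ = √(−1/(2β₂)).

## Worked example

`examples/01_uniform_background_bias.py` simulates 20000 reported presences
of a marginal generalist species (niche optimum −4, breadth 1.5) under a
Gaussian sampling effort centered at 0, and fits with uniform background:

```
true niche:          mu0 = -4.0000   sigma0 = 1.5000
fitted (UB):         mu  = -1.2302   sigma  = 0.8338
product f*s_x:       mu  = -1.2308   sigma  = 0.8321
KL-argmin oracle:    mu  = -1.2308   sigma  = 0.8321
```

The fitted optimum sits ~2.8 environmental units from the truth and the
breadth is nearly halved — exactly on the closed-form product Gaussian
f·s_x, which is what the uniform-background estimator actually targets.
The other examples walk through the target-group scheme (including the
expulsion regime), the effort background, the derivative-based bias
diagnostics, and the scenario grid.

A thin CLI mirrors the library: `nichebias simulate|fit|scenario|grid|diagnose`
(see `--help` on each subcommand).

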