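"""Uniform-background bias: the fit converges to f * s_x, not f.

Simulates reported presences of a marginal generalist species (niche
optimum -4, breadth 1.5) under a Gaussian sampling effort concentrated at
environment 0, fits a log-quadratic Poisson point process model with
uniformly drawn background points, and compares the estimate with the
closed-form product Gaussian that theory predicts.
"""

from nichebias import (
    EffortSpec,
    NicheParams,
    ScenarioSpec,
    gaussian_product,
    run_scenario,
)

niche = NicheParams(mu0=-4.0, sigma0=1.5)
spec = ScenarioSpec(niche, effort="GS", method="UB", seed=20200520)
result = run_scenario(spec)

pred_mu, pred_sd = gaussian_product((niche.mu0, niche.sigma0), (0.0, 1.0))
print(f"true niche:          mu0 = {niche.mu0:.4f}   sigma0 = {niche.sigma0:.4f}")
print(f"fitted (UB):         mu  = {result.fit.mu_hat:.4f}   sigma  = {result.fit.sigma_hat:.4f}")
print(f"product f*s_x:       mu  = {pred_mu:.4f}   sigma  = {pred_sd:.4f}")
print(f"KL-argmin oracle:    mu  = {result.target_mu:.4f}   sigma  = {result.target_sigma:.4f}")
print()
print(
    "The uniform background ignores where observers actually looked, so the\n"
    "fit lands on the product of the niche and the observation density: the\n"
    "optimum is dragged ~2.8 environmental units toward the effort peak and\n"
    "the species looks far more specialized than it is."
)
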