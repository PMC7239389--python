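"""Target-group background: immune to effort, biased by the group itself.

Fits the same species under the same concentrated (GS) sampling effort with
background points drawn as pooled target-group occurrences, for the three
TG concentration levels.  A flat TG density corrects the effort bias; a
concentrated one displaces the estimate toward the quotient f/a, and the
most concentrated one expels the niche from the TG's environmental range.
"""

from nichebias import NicheParams, ScenarioSpec, run_scenario

niche = NicheParams(mu0=-4.0, sigma0=1.5)
print(f"true niche: mu0 = {niche.mu0}, sigma0 = {niche.sigma0}; effort = GS\n")
for tg in ("FLAT", "THICK", "THIN"):
    spec = ScenarioSpec(niche, effort="GS", method="TGOB", tg_shape=tg, seed=20200520)
    r = run_scenario(spec)
    if r.target.proper:
        print(
            f"TG {tg:5s}: fitted mu = {r.fit.mu_hat:7.3f}  sigma = {r.fit.sigma_hat:6.3f}"
            f"   | target f/a argmin: mu = {r.target_mu:7.3f}  sigma = {r.target_sigma:6.3f}"
        )
    else:
        print(
            f"TG {tg:5s}: EXPULSION regime (edge mass {r.target.edge_mass:.2f}) — "
            f"concave fit: {r.fit.valid_sigma}"
        )
print(
    "\nFLAT recovers the true niche whatever the effort; THICK/THIN bias the\n"
    "estimate away from the group's environmental range (quotient target f/a)."
)
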