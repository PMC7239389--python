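"""Derivative-based bias diagnostics on the environmental axis.

Computes, without any simulation, the quantities that predict when each
background scheme is safe: the variation speeds of the observation density
and the niche (uniform-background bias), and the derivative of f/a
(target-group bias and the expulsion geometry).
"""

from nichebias import (
    EffortSpec,
    NicheParams,
    TGShape,
    bias_diagnostics,
    effort_env_density,
    gaussian_niche,
    make_env_grid,
    tg_density,
)

grid = make_env_grid()
f = gaussian_niche(NicheParams(-1.0, 1.5), grid)

for effort in ("CST", "LIN", "GS"):
    s_x = effort_env_density(EffortSpec(effort), grid)
    rep = bias_diagnostics(f, s_x)
    print(
        f"effort {effort:3s}: max|ds_x/dw| = {rep.max_abs_dsx:6.3f}  "
        f"max|df/dw| = {rep.max_abs_df:6.3f}  ratio = {rep.dsx_over_df:6.3f}  "
        f"regime = {rep.regime}"
    )

print()
for tg in ("FLAT", "THICK"):
    a = tg_density(TGShape(tg), grid)
    rep = bias_diagnostics(f, effort_env_density(EffortSpec("CST"), grid), a)
    zeros = ", ".join(f"{w:.2f}" for w in rep.dfa_sign_changes)
    print(f"TG {tg:5s}: d(f/a)/dw changes sign at w = [{zeros}]")

print(
    "\nA small effort-to-niche variation ratio means the uniform-background\n"
    "fit is nearly unbiased; the sign changes of d(f/a)/dw locate where the\n"
    "target-group scheme relocates the estimated optimum."
)
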