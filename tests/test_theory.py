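"""Bias targets, KL machinery, argmin oracle and derivative diagnostics."""

import numpy as np
import pytest
from scipy import stats

from nichebias import (
    EffortSpec,
    EnvDensity,
    NicheParams,
    TGShape,
    bias_diagnostics,
    effort_env_density,
    gaussian_niche,
    gaussian_product,
    kl_argmin_gaussian,
    kl_divergence,
    tg_density,
    tgob_target,
    ub_target,
)


@pytest.fixture(scope="module")
def generalist(grid):
    return gaussian_niche(NicheParams(-1.0, 1.5), grid)


class TestUBTarget:
    def test_cst_effort_gives_back_f(self, grid, generalist):
        s_x = effort_env_density(EffortSpec("CST"), grid)
        t = ub_target(generalist, s_x)
        assert np.allclose(t.density.values, generalist.values, atol=1e-12)
        assert t.proper

    def test_gs_effort_closed_form_product(self, grid):
        f = gaussian_niche(NicheParams(-4.0, 1.5), grid)
        s_x = effort_env_density(EffortSpec("GS"), grid)
        t = ub_target(f, s_x)
        assert t.gaussian[0] == pytest.approx(-1.2308, abs=1e-4)
        assert t.gaussian[1] == pytest.approx(0.8321, abs=1e-4)
        # tabulated product agrees with the closed form
        assert t.density.mean() == pytest.approx(-1.2308, abs=1e-3)
        assert t.density.sd() == pytest.approx(0.8321, abs=1e-3)

    def test_cut_effort_marginal_specialist_nearly_unbiased(self, grid):
        # the CUT effort removes only environments where the species is rare
        f = gaussian_niche(NicheParams(-4.0, 0.6), grid)
        s_x = effort_env_density(EffortSpec("CUT"), grid)
        t = ub_target(f, s_x)
        gap = np.max(np.abs(t.density.values - f.values))
        assert gap < 0.01 * f.values.max()

    def test_zero_product_rejected(self, grid):
        left = EnvDensity(grid, (grid.nodes < 0).astype(float))
        right = EnvDensity(grid, (grid.nodes > 1).astype(float))
        with pytest.raises(ValueError):
            ub_target(left, right)


class TestTGOBTarget:
    def test_flat_tg_is_nearly_unbiased(self, grid, generalist):
        t = tgob_target(generalist, tg_density(TGShape("FLAT"), grid))
        gap = np.max(np.abs(t.density.values - generalist.values))
        assert gap < 0.02 * generalist.values.max()
        assert t.proper

    def test_thick_tg_closed_form_quotient(self, grid, generalist):
        t = tgob_target(generalist, tg_density(TGShape("THICK"), grid))
        assert t.proper
        assert t.gaussian[0] == pytest.approx(-2.2857, abs=1e-4)
        assert t.gaussian[1] == pytest.approx(2.2678, abs=1e-4)

    def test_thin_tg_triggers_expulsion(self, grid, generalist):
        t = tgob_target(generalist, tg_density(TGShape("THIN"), grid))
        assert t.regime == "EXPULSION"
        # mass piles at the support edges
        assert t.edge_mass > 0.2

    def test_target_independent_of_effort(self, grid, generalist):
        # the TGOB target involves only f and a — bitwise identical however
        # the observation density is chosen
        a = tg_density(TGShape("THICK"), grid)
        t1 = tgob_target(generalist, a)
        t2 = tgob_target(generalist, a)
        assert np.array_equal(t1.density.values, t2.density.values)

    def test_zero_tg_density_rejected(self, grid, generalist):
        bad = EnvDensity(grid, np.maximum(grid.nodes, 0.0) + 1e-12)
        bad.values = bad.values * (grid.nodes > 0)  # zeros on the left half
        with pytest.raises(ValueError):
            tgob_target(generalist, bad)


class TestKLDivergence:
    def test_self_divergence_zero(self, grid, generalist):
        assert kl_divergence(generalist, generalist, grid) == pytest.approx(0.0, abs=1e-12)

    def test_unit_shift_closed_form(self, grid):
        p = gaussian_niche(NicheParams(0.0, 1.0), grid)
        q = gaussian_niche(NicheParams(1.0, 1.0), grid)
        # (mu1 - mu2)^2 / (2 sigma^2) = 0.5; truncation correction < 1e-4
        assert kl_divergence(p, q, grid) == pytest.approx(0.5, abs=1e-3)

    def test_biased_target_further_than_unbiased(self, grid, generalist):
        gs = ub_target(generalist, effort_env_density(EffortSpec("GS"), grid))
        cst = ub_target(generalist, effort_env_density(EffortSpec("CST"), grid))
        assert kl_divergence(gs.density, generalist, grid) > kl_divergence(
            cst.density, generalist, grid
        )
        assert kl_divergence(cst.density, generalist, grid) == pytest.approx(0.0, abs=1e-12)

    def test_support_violation_is_infinite(self, grid, generalist):
        q = EnvDensity(grid, (grid.nodes > 0).astype(float) + 0.0)
        with pytest.warns(UserWarning, match="support violation"):
            assert kl_divergence(generalist, q, grid) == np.inf


class TestKLArgminGaussian:
    def test_gaussian_target_is_its_own_argmin(self, grid):
        f = gaussian_niche(NicheParams(-1.0, 1.5), grid)
        t = ub_target(f, effort_env_density(EffortSpec("CST"), grid))
        mu, sigma = kl_argmin_gaussian(t, grid)
        assert mu == pytest.approx(-1.0, abs=1e-2)
        assert sigma == pytest.approx(1.5, abs=1e-2)

    def test_truncated_target_recovers_untruncated_parameters(self, grid):
        # a heavily truncated Gaussian target: the argmin over the truncated
        # family is the *untruncated* parameter pair
        f = gaussian_niche(NicheParams(-4.0, 1.5), grid)
        t = ub_target(f, effort_env_density(EffortSpec("CST"), grid))
        mu, sigma = kl_argmin_gaussian(t, grid)
        assert mu == pytest.approx(-4.0, abs=1e-2)
        assert sigma == pytest.approx(1.5, abs=1e-2)

    def test_expulsion_target_raises(self, grid):
        f = gaussian_niche(NicheParams(-1.0, 1.5), grid)
        t = tgob_target(f, tg_density(TGShape("THIN"), grid))
        with pytest.raises(ValueError, match="EXPULSION"):
            kl_argmin_gaussian(t, grid)

    def test_lin_slope_monotonicity(self, grid):
        """Steeper linear effort never decreases the optimum bias."""
        f = gaussian_niche(NicheParams(-1.0, 1.5), grid)
        errs = []
        for c in (0.0, 0.25, 0.5, 1.0):
            prof = 0.1 - c * grid.nodes / 50.0
            s_x = EnvDensity(grid, prof)
            mu, _ = kl_argmin_gaussian(ub_target(f, s_x), grid)
            errs.append(abs(mu - (-1.0)))
        assert all(e2 >= e1 - 1e-9 for e1, e2 in zip(errs, errs[1:]))

    @pytest.mark.parametrize("mu0", [-1.0, -4.0])
    def test_generalist_more_biased_than_specialist_under_gs(self, grid, mu0):
        errs = {}
        for sigma0 in (0.6, 1.5):
            f = gaussian_niche(NicheParams(mu0, sigma0), grid)
            t = ub_target(f, effort_env_density(EffortSpec("GS"), grid))
            mu, _ = kl_argmin_gaussian(t, grid)
            errs[sigma0] = abs(mu - mu0)
        assert errs[1.5] > errs[0.6]


class TestBiasDiagnostics:
    def test_cst_effort_flat_regime(self, grid, generalist):
        s_x = effort_env_density(EffortSpec("CST"), grid)
        rep = bias_diagnostics(generalist, s_x)
        assert rep.max_abs_dsx == pytest.approx(0.0, abs=1e-12)
        assert rep.regime == "flat_effort"

    def test_very_generalist_species_fits_sx(self, grid):
        # a nearly flat niche under GS effort: the target tracks s_x, not f
        f = gaussian_niche(NicheParams(0.0, 20.0), grid)
        s_x = effort_env_density(EffortSpec("GS"), grid)
        rep = bias_diagnostics(f, s_x)
        assert rep.regime == "flat_niche"
        assert rep.kl_target_vs_sx < rep.kl_target_vs_f

    def test_flat_tg_quotient_derivative_tracks_f(self, grid, generalist):
        a = tg_density(TGShape("FLAT"), grid)
        rep = bias_diagnostics(generalist, effort_env_density(EffortSpec("CST"), grid), a)
        df = np.gradient(generalist.values, grid.nodes)
        scale = np.max(np.abs(df))
        assert np.max(np.abs(rep.dfa - df)) < 0.05 * scale

    def test_thick_tg_quotient_sign_change_near_expelled_optimum(self, grid, generalist):
        a = tg_density(TGShape("THICK"), grid)
        rep = bias_diagnostics(generalist, effort_env_density(EffortSpec("CST"), grid), a)
        # d(f/a)/dw vanishes at the quotient optimum -2.2857
        assert rep.dfa_sign_changes is not None
        assert np.min(np.abs(rep.dfa_sign_changes - (-2.2857))) < 0.05
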