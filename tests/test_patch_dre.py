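import numpy as np
import pytest

from porehr.patch_dre import (
    ConvergenceError,
    DREParams,
    ReactionEnvironment,
    analytic_limit,
    nondimensionalize,
    solve_patch,
)


def make_env(**kw):
    base = dict(
        Dm=2.1e-9, Vm=1e-7, phi=0.5, lambda_c=1e-3, Cs=10.0, Km_s=0.1,
        Km_O2=0.0276, C0=0.276,
    )
    base.update(kw)
    return ReactionEnvironment(**base)


class TestNondimensionalize:
    def test_alpha_is_km_over_c0(self):
        p = nondimensionalize(make_env(Km_O2=0.1 * 0.276), r0=1e-3)
        assert p.alpha == pytest.approx(0.1)

    def test_beta_scales_quadratically_with_radius(self):
        p1 = nondimensionalize(make_env(), r0=1e-3)
        p2 = nondimensionalize(make_env(), r0=2e-3)
        assert p2.beta == pytest.approx(4.0 * p1.beta)

    def test_beta_substrate_saturated_limit(self):
        env = make_env(Cs=1e6, Km_s=0.1)
        p = nondimensionalize(env, r0=1e-3)
        expected = 3 * env.Vm * env.phi * 1e-6 / (env.Dm * env.lambda_c * env.C0)
        assert p.beta == pytest.approx(expected, rel=1e-3)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            nondimensionalize(make_env(), r0=0.0)
        with pytest.raises(ValueError):
            make_env(C0=-1.0)


class TestSolvePatch:
    def test_no_reaction_uniform_profile(self):
        sol = solve_patch(DREParams(alpha=0.1, beta=0.0))
        assert np.allclose(sol.u, 1.0)
        assert sol.respiration == 0.0

    def test_high_alpha_matches_first_order_solution(self):
        """alpha = 10: the linear-kinetics closed form holds within 1%."""
        sol = solve_patch(DREParams(alpha=10.0, beta=1.0))
        ref = analytic_limit(10.0, 1.0, "high_alpha", sol.chi)
        assert np.max(np.abs(sol.u - ref) / ref) < 0.01

    def test_low_alpha_matches_parabola(self):
        """alpha -> 0, beta <= 6: zeroth-order parabola holds within 1%."""
        sol = solve_patch(DREParams(alpha=1e-4, beta=3.0))
        ref = analytic_limit(1e-4, 3.0, "low_alpha", sol.chi)
        assert np.max(np.abs(sol.u - ref) / np.maximum(ref, 1e-2)) < 0.01

    @pytest.mark.parametrize(
        "alpha,beta",
        [(0.1, 0.1), (0.1, 10.0), (0.1, 1000.0), (0.01, 1e5), (0.5, 50.0), (10.0, 100.0)],
    )
    def test_flux_balance(self, alpha, beta):
        """Surface flux equals the volume-integrated sink to 0.1%."""
        sol = solve_patch(DREParams(alpha=alpha, beta=beta))
        assert sol.respiration == pytest.approx(sol.respiration_volume, rel=1e-3)

    def test_monotone_in_beta_and_alpha(self):
        r_beta = [
            solve_patch(DREParams(alpha=0.1, beta=b)).respiration
            for b in (0.1, 1.0, 10.0, 100.0, 1000.0)
        ]
        assert all(a <= b for a, b in zip(r_beta, r_beta[1:]))
        r_alpha = [
            solve_patch(DREParams(alpha=a, beta=10.0)).respiration
            for a in (0.01, 0.1, 0.5, 1.0, 10.0)
        ]
        assert all(a >= b for a, b in zip(r_alpha, r_alpha[1:]))

    @pytest.mark.parametrize("beta", [0.5, 2.0, 6.0, 10.0])
    def test_respiration_within_limiting_envelope(self, beta):
        """For beta <= 10 the respiration lies between the two limiting
        analytic solutions (zeroth-order upper line and the alpha = 10
        first-order lower line), the band the full model is drawn against."""
        r = solve_patch(DREParams(alpha=0.3, beta=beta)).respiration
        chi = np.linspace(0, 1, 400)
        # analytic respiration of the first-order profile: 3 (q coth q - 1)
        q = np.sqrt(beta / 10.0)
        r_lower = 3.0 * (q / np.tanh(q) - 1.0)
        r_upper = beta  # zeroth-order: maximal consumption rate
        assert r_lower - 1e-9 <= r <= r_upper + 1e-9

    def test_surface_localization_at_high_beta(self):
        """beta = 1000: reaction rate at the surface dwarfs the center."""
        sol = solve_patch(DREParams(alpha=0.1, beta=1000.0))
        rate = sol.u / (sol.u + 0.1)
        assert rate[-1] / max(rate[0], 1e-300) > 10.0

    def test_second_order_mesh_convergence(self):
        ref = solve_patch(DREParams(alpha=0.1, beta=50.0), n_nodes=3200).respiration
        errs = [
            abs(solve_patch(DREParams(alpha=0.1, beta=50.0), n_nodes=n).respiration - ref)
            for n in (100, 200, 400)
        ]
        ratios = [errs[i] / errs[i + 1] for i in range(2)]
        assert all(3.0 < r < 5.0 for r in ratios)


class TestAnalyticLimit:
    def test_boundary_condition_both_regimes(self):
        chi = np.array([1.0])
        assert analytic_limit(0.01, 3.0, "low_alpha", chi)[0] == pytest.approx(1.0)
        assert analytic_limit(10.0, 3.0, "high_alpha", chi)[0] == pytest.approx(1.0)

    def test_parabola_center_zero_at_beta_six(self):
        assert analytic_limit(1e-3, 6.0, "low_alpha", np.array([0.0]))[0] == pytest.approx(0.0)

    def test_low_alpha_rejects_beta_above_six(self):
        with pytest.raises(ValueError):
            analytic_limit(1e-3, 6.5, "low_alpha", np.linspace(0, 1, 5))

    def test_high_alpha_equals_sinh_form(self):
        """The exponential form equals sinh(q chi)/(chi sinh q) identically."""
        alpha, beta = 2.0, 8.0
        q = np.sqrt(beta / alpha)
        chi = np.linspace(1e-6, 1.0, 50)
        ref = np.sinh(q * chi) / (chi * np.sinh(q))
        mine = analytic_limit(alpha, beta, "high_alpha", chi)
        assert np.allclose(mine, ref, rtol=1e-10)

    def test_removable_singularity_at_center(self):
        alpha, beta = 1.0, 4.0
        q = np.sqrt(beta / alpha)
        val = analytic_limit(alpha, beta, "high_alpha", np.array([0.0]))[0]
        assert val == pytest.approx(q / np.sinh(q), rel=1e-10)
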