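"""Analytic NCP/power theory: closed forms, optima, counterexample."""

import numpy as np
import pytest
from scipy import integrate, stats

from varhet import (
    ModelParams,
    ResidualSpec,
    beta_gf_for_direct_power,
    binary_factor_conditional_variances,
    direct_test_ncp,
    expected_variance_ncp,
    genotype_variances,
    optimal_beta_f_2df,
    optimal_beta_f_closed,
    power_curves,
    power_from_ncp,
    simulate_trait,
    table1_power,
)


def _params(beta_f=0.0, beta_gf=0.0, p_b=0.5, sigma2_f=1.0, sigma2_eps=1.0, beta_g=0.0):
    return ModelParams(
        beta_g=beta_g, beta_f=beta_f, beta_gf=beta_gf, p_b=p_b, sigma2_f=sigma2_f,
        residual=ResidualSpec(sigma2_eps=sigma2_eps),
    )


class TestGenotypeVariances:
    def test_no_interaction_homogeneity(self):
        v = genotype_variances(_params(beta_f=0.7))
        assert v.var_aa == v.var_ab == v.var_bb == pytest.approx(0.49 + 1.0)

    @pytest.mark.parametrize(
        "beta_f, beta_gf, expected",
        [(1.0, 0.5, (2.0, 3.25, 5.0)), (0.0, 1.0, (1.0, 2.0, 5.0))],
    )
    def test_direct_substitution(self, beta_f, beta_gf, expected):
        v = genotype_variances(_params(beta_f=beta_f, beta_gf=beta_gf))
        assert v.as_array() == pytest.approx(expected)

    @pytest.mark.parametrize("beta_f", [-1.0, 0.0, 0.8])
    @pytest.mark.parametrize("beta_gf", [0.2, 0.6, 1.0])
    @pytest.mark.parametrize("p_b", [0.1, 0.5])
    def test_monte_carlo_agreement(self, beta_f, beta_gf, p_b):
        n = 300_000
        params = _params(beta_f=beta_f, beta_gf=beta_gf, p_b=p_b)
        v = genotype_variances(params).as_array()
        c = simulate_trait(params, n, seed=hash((beta_f, beta_gf, p_b)) % 2**31)
        for j in range(3):
            nj = int((c.g == j).sum())
            if nj < 100:
                continue
            sample = c.y[c.g == j].var(ddof=1)
            assert abs(sample - v[j]) < 3.5 * v[j] * np.sqrt(2 / nj)


class TestDirectTestNcp:
    def test_zero_interaction(self):
        res = direct_test_ncp(_params(), 10_000, alpha=0.05)
        assert res.ncp == 0.0
        assert res.power == pytest.approx(0.05)

    def test_direct_evaluation(self):
        res = direct_test_ncp(_params(beta_gf=0.0909, p_b=0.05), 10_000)
        assert res.ncp == pytest.approx(0.0909**2 * 10_000 * 0.095, rel=1e-12)
        assert res.ncp == pytest.approx(7.85, abs=0.01)

    @pytest.mark.parametrize("p_b", [0.05, 0.2, 0.45])
    def test_allele_frequency_symmetry(self, p_b):
        a = direct_test_ncp(_params(beta_gf=0.3, p_b=p_b), 5_000).ncp
        b = direct_test_ncp(_params(beta_gf=0.3, p_b=1 - p_b), 5_000).ncp
        assert a == pytest.approx(b, rel=1e-12)

    @pytest.mark.parametrize("p_b", np.linspace(0.05, 0.95, 7))
    def test_orthogonalized_variance_identity(self, p_b):
        """var(gF) - cov(F,gF)^2/var(F) reduces to 2 P_B (1-P_B) var(F)."""
        s2f = 1.7
        var_gf = 2 * p_b * (1 + p_b) * s2f
        cov = 2 * p_b * s2f
        assert var_gf - cov**2 / s2f == pytest.approx(2 * p_b * (1 - p_b) * s2f, rel=1e-12)


class TestExpectedVarianceNcp:
    def test_zero_interaction_gives_zero(self):
        for contrast in ("2df", "AA_vs_rest", "AB_vs_rest", "BB_vs_rest"):
            assert expected_variance_ncp(_params(beta_f=1.0), 10_000, contrast).ncp == (
                pytest.approx(0.0, abs=1e-9)
            )

    def test_m_shaped_in_beta_f(self):
        """Two local maxima with a local minimum between them."""
        grid = np.linspace(-4, 4, 801)
        ncps = np.array(
            [expected_variance_ncp(_params(beta_f=b, beta_gf=0.5, p_b=0.3), 10_000).ncp
             for b in grid]
        )
        interior = (ncps[1:-1] > ncps[:-2]) & (ncps[1:-1] > ncps[2:])
        maxima = grid[1:-1][interior]
        assert len(maxima) == 2
        between = (grid > maxima[0]) & (grid < maxima[1])
        assert ncps[np.searchsorted(grid, maxima[0]):np.searchsorted(grid, maxima[1])].min() < min(
            ncps[np.searchsorted(grid, m)] for m in maxima
        )

    def test_simulation_agreement(self):
        """Mean simulated Bartlett statistic ~ df + analytic NCP."""
        params = _params(beta_f=1.0, beta_gf=0.5, p_b=0.5)
        analytic = expected_variance_ncp(params, 10_000, "2df").ncp
        from varhet.experiments import ncp_validation

        rec = ncp_validation(params, 10_000, reps=400, seed=31)
        assert abs(rec["mean_stat_minus_df"] - analytic) < 3.5 * rec["mc_se"]

    def test_one_df_contrasts_nonnegative_and_below_2df_sum(self):
        params = _params(beta_f=0.8, beta_gf=0.4, p_b=0.3)
        for contrast in ("AA_vs_rest", "AB_vs_rest", "BB_vs_rest"):
            assert expected_variance_ncp(params, 10_000, contrast).ncp >= 0


class TestClosedFormOptima:
    def test_aa_vs_ab_roots(self):
        opt = optimal_beta_f_closed(1.0, 1.0, 1.0, "AA_vs_AB")
        assert sorted(opt.roots) == pytest.approx(
            sorted(((-1 + np.sqrt(5)) / 2, (-1 - np.sqrt(5)) / 2)), rel=1e-12
        )

    def test_ab_vs_bb_roots(self):
        opt = optimal_beta_f_closed(1.0, 1.0, 1.0, "AB_vs_BB")
        assert sorted(opt.roots) == pytest.approx(
            sorted(((-3 + np.sqrt(5)) / 2, (-3 - np.sqrt(5)) / 2)), rel=1e-12
        )

    def test_roots_satisfy_quadratics_exactly(self):
        for bgf in (0.1, 0.5, 1.3):
            for s2e, s2f in ((1.0, 1.0), (2.0, 0.5)):
                c = s2e / s2f
                for r in optimal_beta_f_closed(bgf, s2e, s2f, "AA_vs_AB").roots:
                    assert r**2 + bgf * r - c == pytest.approx(0.0, abs=1e-12)
                for r in optimal_beta_f_closed(bgf, s2e, s2f, "AB_vs_BB").roots:
                    assert r**2 + 3 * bgf * r + 2 * bgf**2 - c == pytest.approx(0.0, abs=1e-12)

    def test_small_interaction_limit(self):
        roots = optimal_beta_f_closed(1e-9, 1.0, 1.0, "AA_vs_AB").roots
        assert sorted(roots) == pytest.approx([-1.0, 1.0], abs=1e-6)


class TestNumeric2dfOptimum:
    def test_flat_objective_rejected(self):
        with pytest.raises(ValueError):
            optimal_beta_f_2df(_params(beta_gf=0.0), 10_000)

    def test_small_interaction_limit(self):
        opt = optimal_beta_f_2df(_params(beta_gf=0.01, p_b=0.3), 10_000)
        assert min(abs(opt.roots[0] - 1.0), abs(opt.roots[0] + 1.0)) < 0.05

    def test_optimality_certificate(self, rng):
        params = _params(beta_gf=0.4, p_b=0.2)
        opt = optimal_beta_f_2df(params, 10_000)
        best = expected_variance_ncp(
            _params(beta_f=opt.roots[0], beta_gf=0.4, p_b=0.2), 10_000
        ).ncp
        probes = rng.uniform(-10, 10, size=300)
        for b in probes:
            assert expected_variance_ncp(
                _params(beta_f=b, beta_gf=0.4, p_b=0.2), 10_000
            ).ncp <= best + 1e-9


class TestPowerFromNcp:
    def test_zero_ncp_gives_alpha(self):
        assert power_from_ncp(0.0, 2, 0.05) == 0.05

    def test_standard_calibration_point(self):
        assert power_from_ncp(7.849, 1, 0.05) == pytest.approx(0.80, abs=1e-3)

    def test_agrees_with_numeric_integration(self):
        # independent route: integrate the noncentral chi2 density
        ncp, df, alpha = 5.0, 2, 0.05
        crit = stats.chi2.isf(alpha, df)
        val, _ = integrate.quad(lambda x: stats.ncx2.pdf(x, df, ncp), crit, np.inf)
        assert power_from_ncp(ncp, df, alpha) == pytest.approx(val, rel=1e-8)

    def test_strictly_increasing_in_ncp(self):
        powers = [power_from_ncp(ncp, 2, 0.05) for ncp in np.linspace(0, 30, 40)]
        assert np.all(np.diff(powers) > 0)


class TestBetaGfForDirectPower:
    def test_target_equal_alpha_gives_zero(self):
        assert beta_gf_for_direct_power(0.3, 10_000, 0.05, 0.05) == 0.0

    def test_reference_value(self):
        bgf = beta_gf_for_direct_power(0.05, 10_000, 0.05, 0.8)
        assert bgf == pytest.approx(0.0909, abs=2e-4)

    @pytest.mark.parametrize("p_b, alpha", [(0.05, 0.05), (0.4, 0.01), (0.2, 5e-8)])
    def test_round_trip(self, p_b, alpha):
        bgf = beta_gf_for_direct_power(p_b, 10_000, alpha, 0.8)
        res = direct_test_ncp(_params(beta_gf=bgf, p_b=p_b), 10_000, alpha=alpha)
        assert res.power == pytest.approx(0.8, abs=1e-8)


class TestTable1:
    def test_symmetry_in_allele_frequency(self):
        for p_b in (0.05, 0.4):
            assert table1_power(p_b, 0.05) == pytest.approx(
                table1_power(1 - p_b, 0.05), abs=0.01
            )

    def test_n_invariance_of_construction(self):
        """beta_gf^2*N is pinned by the direct-power constraint, so the
        variance-test power is nearly independent of N."""
        assert table1_power(0.4, 0.01, n=10_000) == pytest.approx(
            table1_power(0.4, 0.01, n=100_000), abs=0.005
        )


class TestBinaryFactorCounterexample:
    def test_no_interaction_equal(self):
        v0, v1 = binary_factor_conditional_variances(0.7, 0.0, 0.3)
        assert v0 == v1

    def test_blind_spot_equality(self):
        """beta_f = -beta_gf/2 equalizes the variances despite interaction."""
        v0, v1 = binary_factor_conditional_variances(-0.5, 1.0, 0.5)
        assert (v0, v1) == pytest.approx((1.25, 1.25))

    def test_direct_substitution(self):
        assert binary_factor_conditional_variances(0.0, 1.0, 0.5) == pytest.approx((1.0, 2.0))

    def test_marginal_mean_gap_when_f_asymmetric(self):
        """With f != 1/2 the blind spot still shifts the genotype means."""
        bgf, f = 1.0, 0.3
        bf = -bgf / 2
        e_f = f - (1 - f)  # E[F] on {-1,+1}
        mean0 = bf * e_f
        mean1 = (bf + bgf) * e_f
        assert mean0 != pytest.approx(mean1)


@pytest.fixture(scope="module")
def curves():
    return power_curves(
        beta_f_values=np.linspace(-2, 2, 9), beta_gf_values=[0.1, 0.5, 1.0],
        p_b_values=[0.05, 0.4], n=10_000, alpha=0.05,
    )


class TestPowerCurves:

    def test_direct_power_constant_in_beta_f(self, curves):
        direct = curves[curves.test == "direct"]
        for _, grp in direct.groupby(["beta_gf", "p_b"]):
            assert grp.power.nunique() == 1

    def test_variance_ncp_envelope_grows_with_interaction(self, curves):
        """The best-case (over beta_f) variance-test NCP rises with beta_gf.

        Pointwise in beta_f the ordering can invert near the cancellation
        beta_f ~ -beta_gf, so the claim is about the attainable maximum.
        """
        var2 = curves[(curves.test == "variance") & (curves.contrast == "2df")]
        for _, grp in var2.groupby("p_b"):
            envelope = grp.groupby("beta_gf").ncp.max().sort_index().to_numpy()
            assert np.all(np.diff(envelope) > 0)

    def test_direct_dominates_variance_test(self, curves):
        merged = curves[(curves.test == "variance") & (curves.contrast == "2df")].merge(
            curves[curves.test == "direct"], on=["beta_f", "beta_gf", "p_b"],
            suffixes=("_var", "_dir"),
        )
        assert (merged.power_dir >= merged.power_var - 1e-9).all()
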