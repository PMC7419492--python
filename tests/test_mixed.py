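"""REML engine: covariance construction, estimation, Wald tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from mppme import (
    VcovSpec,
    bonferroni_threshold,
    build_vcov,
    neglog10p_chi2,
    reml_fit,
    wald_test,
)


class TestBuildVcov:
    def _two_cross_spec(self):
        # one genotype per cross, each seen in two environments; order:
        # (g1,c1,e1), (g2,c2,e1), (g1,c1,e2), (g2,c2,e2)
        return VcovSpec.cs_ecse(
            genotype=["g1", "g2", "g1", "g2"],
            cross=["c1", "c2", "c1", "c2"],
            env=["e1", "e1", "e2", "e2"],
        )

    def test_cs_ecse_pattern(self):
        """The 4x4 covariance of two genotypes from different crosses in two
        environments: sigma_g^2 + cell variance on the diagonal, sigma_g^2
        linking the same genotype across environments, zero between
        crosses."""
        spec = self._two_cross_spec()
        s2g = 3.0
        cells = {"c1:e1": 1.0, "c2:e1": 2.0, "c1:e2": 4.0, "c2:e2": 8.0}
        params = [s2g] + [cells[name] for name in spec.stratum_names]
        V = build_vcov(spec, params)
        expected = np.array(
            [
                [s2g + 1.0, 0.0, s2g, 0.0],
                [0.0, s2g + 2.0, 0.0, s2g],
                [s2g, 0.0, s2g + 4.0, 0.0],
                [0.0, s2g, 0.0, s2g + 8.0],
            ]
        )
        np.testing.assert_array_equal(V, expected)

    def test_zero_genetic_variance_is_diagonal(self):
        spec = self._two_cross_spec()
        V = build_vcov(spec, [0.0, 1.0, 2.0, 3.0, 4.0])
        assert np.count_nonzero(V - np.diag(np.diag(V))) == 0

    def test_homogeneous_errors_scalar_identity(self):
        spec = self._two_cross_spec()
        V = build_vcov(spec, [0.0, 2.5, 2.5, 2.5, 2.5])
        np.testing.assert_array_equal(V, 2.5 * np.eye(4))

    def test_negative_parameter_rejected(self):
        with pytest.raises(ValueError):
            build_vcov(VcovSpec.iid(3), [-1.0])


class TestRemlFit:
    def test_iid_intercept_closed_form(self):
        rng = np.random.default_rng(0)
        y = rng.normal(10.0, 2.0, 50)
        X = pd.DataFrame({"intercept": np.ones(50)})
        fit = reml_fit(y, X, VcovSpec.iid(50))
        assert fit.beta["intercept"] == pytest.approx(y.mean(), abs=1e-6)
        assert fit.varcomps["resid:all"] == pytest.approx(y.var(ddof=1), rel=1e-4)

    def test_cross_specific_closed_form(self):
        """With cross fixed effects and cross-specific variances the REML
        problem separates: each variance is the within-cross sample variance
        with the (n_c - 1) divisor."""
        rng = np.random.default_rng(1)
        y = np.concatenate([rng.normal(5, 1, 30), rng.normal(9, 1, 25)])
        cross = ["A"] * 30 + ["B"] * 25
        X = pd.DataFrame(
            {
                "intercept": np.ones(55),
                "cross[B]": np.array([c == "B" for c in cross], dtype=float),
            }
        )
        fit = reml_fit(y, X, VcovSpec.cross_specific(cross))
        assert fit.beta["intercept"] == pytest.approx(y[:30].mean(), abs=1e-5)
        assert fit.varcomps["resid:A"] == pytest.approx(y[:30].var(ddof=1), rel=1e-4)
        assert fit.varcomps["resid:B"] == pytest.approx(y[30:].var(ddof=1), rel=1e-4)

    def test_reml_beats_grid_oracle(self):
        """The optimized restricted likelihood is at least as high as on any
        point of a coarse grid over the variance parameters."""
        rng = np.random.default_rng(2)
        n_groups, per = 12, 4
        u = rng.normal(0, np.sqrt(3.0), n_groups)
        y = 2.0 + np.repeat(u, per) + rng.normal(0, 1.0, n_groups * per)
        Z = np.kron(np.eye(n_groups), np.ones((per, 1)))
        spec = VcovSpec.iid(n_groups * per).with_random("group", Z)
        X = pd.DataFrame({"intercept": np.ones(n_groups * per)})
        fit = reml_fit(y, X, spec)

        def nll(s2u, s2e):
            V = build_vcov(spec, [s2u, s2e])
            Vi = np.linalg.inv(V)
            Xm = X.to_numpy()
            XtViX = Xm.T @ Vi @ Xm
            beta = np.linalg.solve(XtViX, Xm.T @ Vi @ y)
            r = y - Xm @ beta
            return -0.5 * (
                np.linalg.slogdet(V)[1]
                + np.linalg.slogdet(XtViX)[1]
                + float(r @ Vi @ r)
            )

        grid = np.linspace(0.05, 8.0, 12)
        best_grid = max(nll(a, b) for a in grid for b in grid)
        assert fit.reml_loglik >= best_grid - 1e-6

    def test_cs_ecse_variance_recovery(self):
        """Average recovered genotype variance over replicates stays within
        30% of the truth (sigma_g^2 = 4, sigma_eps^2 = 1, n = 300)."""
        s2g_hats = []
        for rep in range(100):
            rng = np.random.default_rng(100 + rep)
            n_geno = 150
            g = rng.normal(0, 2.0, n_geno)
            y = np.concatenate([g + rng.normal(0, 1.0, n_geno) for _ in range(2)])
            genotype = [f"g{i}" for i in range(n_geno)] * 2
            cross = (["A"] * 75 + ["B"] * 75) * 2
            env = ["e1"] * n_geno + ["e2"] * n_geno
            spec = VcovSpec.cs_ecse(genotype, cross, env)
            X = pd.DataFrame({"intercept": np.ones(2 * n_geno)})
            fit = reml_fit(y, X, spec)
            s2g_hats.append(fit.varcomps["genotype_cs"])
        assert np.mean(s2g_hats) == pytest.approx(4.0, rel=0.3)


class TestWald:
    def _fit_with_cov(self, beta, cov):
        names = [f"b{i}" for i in range(len(beta))]
        from mppme.mixed import MixedFit

        return MixedFit(
            beta=pd.Series(beta, index=names),
            cov_beta=pd.DataFrame(cov, index=names, columns=names),
            varcomps={},
            reml_loglik=0.0,
            n_obs=10,
            converged=True,
            spec=VcovSpec.iid(10),
        )

    def test_zero_vector_gives_p_one(self):
        fit = self._fit_with_cov([0.0, 0.0], np.eye(2))
        w = wald_test(fit, ["b0", "b1"])
        assert w.W == 0.0
        assert w.p == 1.0
        assert w.neglog10p == 0.0

    def test_scalar_closed_form(self):
        fit = self._fit_with_cov([2.0], np.eye(1))
        w = wald_test(fit, ["b0"])
        assert w.W == pytest.approx(4.0)
        assert w.df == 1
        assert w.p == pytest.approx(stats.chi2.sf(4.0, 1))

    def test_singular_subcovariance_reduces_df(self):
        cov = np.array([[1.0, 1.0], [1.0, 1.0]])
        fit = self._fit_with_cov([1.0, 1.0], cov)
        w = wald_test(fit, ["b0", "b1"])
        assert w.df == 1


class TestDfAccounting:
    def test_main_vs_environment_specific_df(self):
        """A QTL term with n_a alleles uses n_a - 1 df when tested as a main
        effect (M1) and N_e (n_a - 1) df when environment-specific (M3)."""
        from mppme import build_designs, build_method_data, wald_test
        from mppme import SimConfig, simulate_experiment

        # a 5-allele case: 4 peripheral parents + the central parent

        cfg = SimConfig(
            n_parents=5, cross_sizes=20, n_chromosomes=1, chrom_length_cM=20.0,
            marker_density=0.2, n_environments=2, seed=21,
        )
        exp5 = simulate_experiment(cfg)
        designs = build_designs("parental", exp5.gmap, exp5.geno, exp5.crosses)
        marker = exp5.gmap.markers[0]
        md1 = build_method_data("M1", exp5.plots)
        md3 = build_method_data("M3", exp5.plots)
        X1 = pd.concat([md1.base_X, md1.qtl_columns(designs[marker])], axis=1)
        X3 = pd.concat([md3.base_X, md3.qtl_columns(designs[marker])], axis=1)
        fit1 = reml_fit(md1.y, X1, md1.spec)
        fit3 = reml_fit(md3.y, X3, md3.spec)
        w1 = wald_test(fit1, [c for c in X1.columns if c.startswith("qtl[")])
        w3 = wald_test(fit3, [c for c in X3.columns if c.startswith("qtl[")])
        assert w1.df == 4
        assert w3.df == 8


class TestPvalues:
    @pytest.mark.parametrize(
        "W,df,expected",
        [(44.3, 4, 8.3), (89.2, 8, 15.2), (64.1, 9, 9.7), (78.4, 18, 8.8)],
    )
    def test_reference_conversions(self, W, df, expected):
        assert round(neglog10p_chi2(W, df), 1) == expected

    def test_zero_statistic(self):
        for df in (1, 5, 20):
            assert neglog10p_chi2(0.0, df) == 0.0

    def test_extreme_statistic_is_finite(self):
        val = neglog10p_chi2(1500.0, 4)
        assert np.isfinite(val) and val > 300

    @pytest.mark.parametrize("W,df", [(3.0, 1), (10.0, 4), (45.0, 8), (60.0, 3)])
    def test_matches_numerical_integration(self, W, df):
        p_num, _ = integrate.quad(lambda x: stats.chi2.pdf(x, df), W, np.inf)
        assert neglog10p_chi2(W, df) == pytest.approx(-np.log10(p_num), rel=1e-6)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        w1=st.floats(0.0, 500.0),
        dw=st.floats(0.01, 100.0),
        df=st.integers(1, 30),
    )
    def test_monotone_in_statistic(self, w1, dw, df):
        """A larger chi-square statistic never becomes less significant."""
        assert neglog10p_chi2(w1 + dw, df) >= neglog10p_chi2(w1, df)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(n=st.integers(1, 10**6), k=st.integers(2, 50))
    def test_bonferroni_monotone_in_test_count(self, n, k):
        """More tests always raise the significance bar."""
        assert bonferroni_threshold(n * k) > bonferroni_threshold(n)

    def test_bonferroni_values(self):
        assert round(bonferroni_threshold(5949, 0.05), 2) == 5.08
        assert bonferroni_threshold(1, 0.05) == pytest.approx(1.301, abs=1e-3)
        assert bonferroni_threshold(100, 0.05) == pytest.approx(
            np.log10(2000), abs=1e-12
        )
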