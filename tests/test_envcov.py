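"""QTL-by-environment sensitivity decomposition and allele contrasts."""

import numpy as np
import pandas as pd
import pytest

from mppme import (
    EnvCovariate,
    QtlTruth,
    SensitivityFit,
    SimConfig,
    allele_contrast,
    fit_sensitivity,
    reml_fit,
    simulate_experiment,
    wald_test,
)
from mppme.pipeline import build_designs, build_method_data


def _published_fit():
    """Sensitivity coefficients in the layout of a published five-allele
    example (main effect and precipitation sensitivity per ancestral
    allele)."""
    coeffs = pd.DataFrame(
        {
            "beta": [0.0, -0.75, 2.02, 1.82, -9.02],
            "gamma": [0.0, -0.06, -0.12, -0.03, 0.17],
            "se_beta": [0.0, 1.07, 1.39, 1.44, 4.6],
            "se_gamma": [0.0, 0.03, 0.04, 0.04, 0.14],
        },
        index=["A", "B", "C", "D", "E"],
    )
    cov = EnvCovariate(
        {"LaCoruna": 35.0, "Roggenstein": 77.0, "Ploudaniel": 63.0, "Einbeck": 68.0},
        name="precipitation",
        reference_environment="LaCoruna",
    )
    return SensitivityFit.from_coefficients(coeffs, cov, "A")


class TestAlleleContrast:
    def test_reference_versus_b_at_reference_site(self):
        fit = _published_fit()
        value, _ = allele_contrast(fit, "B", Z=0.0)
        assert round(value, 2) == 1.50

    def test_reference_versus_b_with_more_precipitation(self):
        fit = _published_fit()
        value, _ = allele_contrast(fit, "B", Z=33.0)
        assert round(value, 2) == 5.46

    def test_zero_sensitivity_constant_in_z(self):
        fit = _published_fit()
        fit.table.loc["D", "gamma"] = 0.0
        for z in (0.0, 20.0, 50.0):
            value, _ = allele_contrast(fit, "D", z)
            assert value == pytest.approx(-2 * fit.table.loc["D", "beta"])

    def test_affine_in_z_with_slope_minus_two_gamma(self):
        fit = _published_fit()
        v0, _ = allele_contrast(fit, "C", 0.0)
        v1, _ = allele_contrast(fit, "C", 1.0)
        v10, _ = allele_contrast(fit, "C", 10.0)
        slope = v1 - v0
        assert slope == pytest.approx(-2 * fit.table.loc["C", "gamma"])
        assert v10 == pytest.approx(v0 + 10 * slope)

    def test_se_at_reference_is_twice_se_beta(self):
        fit = _published_fit()
        _, se = allele_contrast(fit, "B", 0.0)
        assert se == pytest.approx(2 * 1.07)

    def test_unknown_allele_raises(self):
        with pytest.raises(KeyError):
            allele_contrast(_published_fit(), "Z", 0.0)


@pytest.fixture(scope="module")
def sensitivity_experiment():
    """Three environments, covariate-driven QTL: beta = -1, gamma = 0.1 for
    every peripheral allele."""
    cfg = SimConfig(
        n_parents=4, cross_sizes=60, n_chromosomes=1, chrom_length_cM=60.0,
        marker_density=0.15, n_environments=3,
        env_covariate=[35.0, 55.0, 77.0],
        qtls=[
            QtlTruth(1, 30.0,
                     beta={"P1": -1.0, "P2": -1.0, "P3": -1.0},
                     gamma={"P1": 0.1, "P2": 0.1, "P3": 0.1})
        ],
        seed=33,
    )
    exp = simulate_experiment(cfg)
    designs = build_designs("parental", exp.gmap, exp.geno, exp.crosses)
    md = build_method_data("M3", exp.plots)
    marker = exp.gmap.table[
        (exp.gmap.table["chromosome"] == 1)
    ].iloc[(exp.gmap.table["position_cM"] - 30.0).abs().argmin()]["marker"]
    return exp, designs, md, marker


class TestFitSensitivity:
    def test_reference_allele_is_zero(self, sensitivity_experiment):
        exp, designs, md, marker = sensitivity_experiment
        fit = fit_sensitivity(md, designs[marker], exp.covariate)
        ref = fit.table.loc[fit.reference_allele]
        assert ref["beta"] == 0.0 and ref["gamma"] == 0.0

    def test_constant_covariate_rejected(self, sensitivity_experiment):
        exp, designs, md, marker = sensitivity_experiment
        flat = EnvCovariate({e: 50.0 for e in exp.config.environments},
                            reference_environment="E1")
        with pytest.raises(ValueError, match="inestimable"):
            fit_sensitivity(md, designs[marker], flat)

    def test_two_environment_reparameterization_identity(self):
        """With two environments and no residual QTLxE term, beta_a + Z_e
        gamma_a reproduces the saturated per-environment effects exactly."""
        cfg = SimConfig(
            n_parents=3, cross_sizes=50, n_chromosomes=1, chrom_length_cM=40.0,
            marker_density=0.5, n_environments=2,
            env_covariate=[35.0, 70.0],
            qtls=[QtlTruth(1, 20.0, effects={"P1": [2.0, -3.0],
                                             "P2": [1.0, 4.0]})],
            seed=44,
        )
        exp = simulate_experiment(cfg)
        designs = build_designs("parental", exp.gmap, exp.geno, exp.crosses)
        md = build_method_data("M3", exp.plots)
        marker = exp.gmap.markers[10]
        sens = fit_sensitivity(md, designs[marker], exp.covariate)
        # saturated fit at the same position
        X = pd.concat([md.base_X, md.qtl_columns(designs[marker])], axis=1)
        sat = reml_fit(md.y, X, md.spec)
        z = exp.covariate.centered()
        for a in designs[marker].allele_labels:
            for e in md.envs:
                expected = float(sat.beta[f"qtl[{a}]@{e}"])
                got = sens.table.loc[a, "beta"] + z[e] * sens.table.loc[a, "gamma"]
                assert got == pytest.approx(expected, abs=1e-4)

    def test_gamma_coverage_when_truth_is_zero(self):
        """Planted gamma = 0: the estimate falls within 2 SE of zero at
        roughly the nominal 95% rate."""
        hits = 0
        n_rep = 60
        for rep in range(n_rep):
            cfg = SimConfig(
                n_parents=3, cross_sizes=40, n_chromosomes=1,
                chrom_length_cM=20.0, marker_density=0.5, n_environments=3,
                env_covariate=[35.0, 55.0, 77.0],
                qtls=[QtlTruth(1, 10.0, beta={"P1": 3.0, "P2": 3.0},
                               gamma={"P1": 0.0, "P2": 0.0})],
                seed=1000 + rep,
            )
            exp = simulate_experiment(cfg)
            designs = build_designs("parental", exp.gmap, exp.geno, exp.crosses)
            md = build_method_data("M3", exp.plots)
            marker = exp.gmap.markers[2]
            sens = fit_sensitivity(md, designs[marker], exp.covariate)
            row = sens.table.loc["P1"]
            if abs(row["gamma"]) <= 2.0 * row["se_gamma"]:
                hits += 1
        assert hits / n_rep >= 0.87

    def test_low_frequency_allele_flagged(self, sensitivity_experiment):
        exp, designs, md, marker = sensitivity_experiment
        fit = fit_sensitivity(md, designs[marker], exp.covariate,
                              min_carriers=1000)
        assert fit.table.loc["P1", "flagged"]
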