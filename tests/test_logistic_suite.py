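"""Logistic suite: likelihood arithmetic, preprocessing, enumeration, LRT."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import skew

from plasmapet import (
    GeneratorConfig,
    ModelSpec,
    enumerate_models,
    fit_logistic,
    fit_model_family,
    generate_cohort,
    likelihood_ratio_test,
    preprocess_predictors,
)
from plasmapet.logistic_suite import (
    bic_from_aic,
    intercept_only_loglik,
    lrt_chi2_vs_null_from_aic,
    model_summary_table,
    pseudo_r2_map,
)
from plasmapet.synthetic_cohort import abeta_binary


@pytest.fixture(scope="module")
def design_and_outcome(default_cohort):
    return preprocess_predictors(default_cohort), abeta_binary(default_cohort)


class TestPreprocess:
    def test_continuous_columns_centered(self, design_and_outcome):
        design, _ = design_and_outcome
        for col in ["age", "gfap", "ptau181", "nfl", "abeta42_40_ipms"]:
            assert abs(design[col].mean()) < 1e-10

    def test_log_reduces_gfap_skewness(self, default_cohort):
        design = preprocess_predictors(default_cohort)
        raw_skew = abs(skew(default_cohort["gfap"]))
        log_skew = abs(skew(design["gfap"]))
        assert log_skew < raw_skew
        assert design.attrs["transforms"]["gfap"] == "log"

    def test_binary_coding(self, default_cohort):
        design = preprocess_predictors(default_cohort)
        assert set(design["sex_female"].unique()) <= {0.0, 1.0}
        assert set(design["diagnosis_ci"].unique()) <= {0.0, 1.0}

    def test_log_of_nonpositive_raises_with_column_name(self, default_cohort):
        bad = default_cohort.copy()
        bad.loc[bad.index[0], "gfap"] = -1.0
        with pytest.raises(ValueError, match="gfap"):
            preprocess_predictors(bad)

    def test_centering_invariance_of_fit(self, default_cohort):
        """Shifting predictors is absorbed by the intercept: likelihood,
        criteria and fitted probabilities are unchanged."""
        y = abeta_binary(default_cohort)
        spec = ModelSpec(("A", "G"), covariates=("age", "sex_female",
                                                 "apoe_carrier", "diagnosis_ci"))
        centered = preprocess_predictors(default_cohort)
        shifted = centered.copy()
        for col in ["age", "gfap", "abeta42_40_ipms"]:
            shifted[col] = shifted[col] + 37.0
        f1 = fit_logistic(centered, y, spec)
        f2 = fit_logistic(shifted, y, spec)
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-6)
        assert f1.aic == pytest.approx(f2.aic, abs=1e-6)
        assert f1.roc.auc == pytest.approx(f2.roc.auc, abs=1e-9)
        np.testing.assert_allclose(
            f1.fitted_probabilities, f2.fitted_probabilities, atol=1e-8
        )


class TestLikelihoodArithmetic:
    def test_intercept_only_closed_form(self):
        y = np.r_[np.ones(60), np.zeros(58)]
        ll0 = intercept_only_loglik(y)
        assert ll0 == pytest.approx(-81.78, abs=0.01)
        assert 2 * 1 - 2 * ll0 == pytest.approx(165.55, abs=0.01)

    def test_aic_bic_identity_on_every_fit(self, default_cohort):
        fits = fit_model_family(default_cohort, "all", "IP-MS")
        for fm in fits.values():
            assert fm.aic == pytest.approx(2 * fm.k - 2 * fm.loglik, abs=1e-9)
            assert fm.bic == pytest.approx(
                fm.k * np.log(fm.n) - 2 * fm.loglik, abs=1e-9
            )
            assert fm.bic - fm.aic == pytest.approx(
                fm.k * (np.log(fm.n) - 2.0), abs=1e-9
            )

    def test_bic_from_aic_helper(self):
        assert bic_from_aic(124.2, 7, 118) == pytest.approx(143.6, abs=0.05)

    def test_lrt_chi2_from_aic_helper(self):
        assert lrt_chi2_vs_null_from_aic(124.2, 7, 60, 58) == pytest.approx(
            53.3, abs=0.1
        )

    def test_nested_loglik_monotone(self, default_cohort):
        fits = fit_model_family(default_cohort, "all", "IP-MS")
        for name, fm in fits.items():
            for other, fo in fits.items():
                if set(other) < set(name):
                    assert fm.loglik >= fo.loglik - 1e-6

    def test_lrt_identity_with_aic(self, default_cohort):
        fits = fit_model_family(default_cohort, "all", "IP-MS")
        small, large = fits["G"], fits["AG"]
        chi2, df, p = likelihood_ratio_test(small, large)
        assert chi2 == pytest.approx((small.aic - large.aic) + 2 * df, abs=1e-9)
        assert df == 1

    def test_lrt_self_is_null(self, default_cohort):
        fits = fit_model_family(default_cohort, "all", "IP-MS")
        chi2, df, p = likelihood_ratio_test(fits["AG"], fits["AG"])
        assert (chi2, df, p) == (0.0, 0, 1.0)

    def test_lrt_non_nested_raises(self, default_cohort):
        fits = fit_model_family(default_cohort, "all", "IP-MS")
        with pytest.raises(ValueError, match="not nested"):
            likelihood_ratio_test(fits["A"], fits["G"])


class TestPseudoR2:
    def test_null_vs_itself_zero(self):
        r2 = pseudo_r2_map(-81.78, -81.78, n=118, k=1)
        assert r2["mcfadden"] == 0.0 and r2["cox_snell"] == 0.0
        assert r2["nagelkerke"] == 0.0

    def test_perfect_fit_nagelkerke_one(self):
        r2 = pseudo_r2_map(0.0, -81.78, n=118, k=7)
        assert r2["nagelkerke"] == pytest.approx(1.0)

    def test_paper_implied_likelihoods(self):
        r2 = pseudo_r2_map(-55.1, -81.77441734193008, n=118, k=7)
        assert r2["mcfadden"] == pytest.approx(0.326, abs=0.001)
        assert r2["cox_snell"] == pytest.approx(0.364, abs=0.001)
        assert r2["nagelkerke"] == pytest.approx(0.485, abs=0.001)


class TestEnumerate:
    def test_full_family_has_sixteen(self):
        specs = enumerate_models("AGNP")
        assert len(specs) == 16
        assert specs[0].name == ""
        assert specs[-1].name == "AGNP"

    def test_two_marker_family(self):
        names = [s.name for s in enumerate_models("AG")]
        assert names == ["", "A", "G", "AG"]

    def test_names_canonically_sorted(self):
        assert ModelSpec(("P", "A", "G")).name == "AGP"

    def test_duplicate_codes_rejected(self):
        with pytest.raises(ValueError):
            enumerate_models("AAG")

    def test_population_covariates(self):
        assert "diagnosis_ci" in enumerate_models("A", population="all")[0].covariates
        assert "diagnosis_ci" not in enumerate_models("A", population="CU")[0].covariates


class TestFitEdgeCases:
    @pytest.mark.filterwarnings(
        "ignore::statsmodels.tools.sm_exceptions.PerfectSeparationWarning",
        "ignore::statsmodels.tools.sm_exceptions.ConvergenceWarning",
    )
    def test_perfect_separation_flagged(self):
        rng = np.random.default_rng(0)
        n = 40
        cohort = pd.DataFrame({
            "age": rng.normal(70, 5, n),
            "sex": rng.choice(["F", "M"], n),
            "apoe_carrier": rng.integers(0, 2, n),
            "diagnosis": rng.choice(["CU", "CI"], n),
            "gfap": np.r_[np.full(20, 50.0), np.full(20, 500.0)]
            * rng.uniform(0.95, 1.05, n),
        })
        y = np.r_[np.zeros(20, int), np.ones(20, int)]
        design = preprocess_predictors(cohort)
        fm = fit_logistic(design, y, ModelSpec(("G",)))
        assert fm.separation_flag
        assert not fm.usable

    def test_single_class_outcome_rejected(self, default_cohort):
        design = preprocess_predictors(default_cohort)
        with pytest.raises(ValueError):
            fit_logistic(design, np.ones(len(design)), ModelSpec(("G",)))

    def test_rank_deficient_design_names_aliased(self, default_cohort):
        design = preprocess_predictors(default_cohort)
        design["nfl"] = design["gfap"]  # perfectly aliased
        y = abeta_binary(default_cohort)
        with pytest.raises(ValueError, match="alias"):
            fit_logistic(design, y, ModelSpec(("G", "N")))


def test_parameter_recovery_on_generated_data():
    """A correctly specified logistic model on generator output recovers its
    own coefficients within Monte-Carlo error at n = 5,000."""
    rng = np.random.default_rng(42)
    n = 5000
    cfg = GeneratorConfig(seed=7).with_sizes(n // 2, n // 2)
    cohort = generate_cohort(cfg)
    design = preprocess_predictors(cohort)
    truth = np.array([0.3, -1.2, 0.8])
    X = design[["age", "gfap", "ptau181"]].to_numpy()
    X = (X - X.mean(0)) / X.std(0)
    eta = -0.2 + X @ truth
    y = (rng.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(int)
    std_design = pd.DataFrame(X, columns=["age", "gfap", "ptau181"])
    std_design["sex_female"] = design["sex_female"].to_numpy()
    fm = fit_logistic(
        std_design, y, ModelSpec(("G", "P"), covariates=("age",), population="CU")
    )
    se = np.sqrt(np.diag(np.linalg.inv(
        (std_design[["age", "gfap", "ptau181"]].to_numpy().T
         * (fm.fitted_probabilities * (1 - fm.fitted_probabilities)))
        @ std_design[["age", "gfap", "ptau181"]].to_numpy()
    )))
    est = fm.params[["age", "gfap", "ptau181"]].to_numpy()
    assert np.all(np.abs(est - truth) < 3 * se)


def test_model_summary_table_columns(default_cohort):
    fits = fit_model_family(default_cohort, "all", "IP-MS")
    table = model_summary_table(fits, reference="demographic")
    assert len(table) == 16
    assert "(demographic)" in table.index
    assert {"aic", "bic", "auc", "lrt_chi2_vs_null",
            "lrt_p_vs_demographic"} <= set(table.columns)
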