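"""Generator fidelity: quartile matching, implied AUC, cohort invariants."""

import numpy as np
import pytest
from scipy.stats import norm, pearsonr

from plasmapet import (
    GeneratorConfig,
    GroupDistribution,
    generate_cohort,
    implied_auc,
    lognormal_params_from_quartiles,
)
from plasmapet.definitions import BIOMARKER_COLUMNS, BIOMARKERS
from plasmapet.synthetic_cohort import (
    DEFAULT_BIOMARKER_DISTRIBUTIONS,
    abeta_binary,
    validate_cohort,
)
from plasmapet.roc_delong import auc


@pytest.mark.parametrize(
    "dist, mu, sigma",
    [
        # GFAP in the amyloid-positive group
        (GroupDistribution(164.0, 125.0, 223.0), 5.0999, 0.4291),
        # Abeta42/40 IP-MS in the amyloid-negative group
        (GroupDistribution(0.132, 0.128, 0.141), -2.0250, 0.0717),
    ],
)
def test_quartile_matching_closed_form(dist, mu, sigma):
    got_mu, got_sigma = lognormal_params_from_quartiles(dist)
    assert got_mu == pytest.approx(mu, abs=1e-3)
    assert got_sigma == pytest.approx(sigma, abs=1e-3)


def test_quartile_matching_reproduces_quartile_ratio():
    d = GroupDistribution(11.7, 8.2, 17.2)
    mu, sigma = lognormal_params_from_quartiles(d)
    z75 = norm.ppf(0.75)
    assert np.exp(mu) == pytest.approx(d.median)
    assert np.exp(mu + sigma * z75) / np.exp(mu - sigma * z75) == pytest.approx(
        d.q75 / d.q25
    )


@pytest.mark.parametrize(
    "median,q25,q75",
    [(-1.0, 0.5, 2.0), (1.0, 2.0, 3.0), (1.0, 0.5, 0.9)],
)
def test_invalid_quartiles_rejected(median, q25, q75):
    with pytest.raises(ValueError):
        GroupDistribution(median, q25, q75)


class TestImpliedAuc:
    def test_identical_distributions_give_half(self):
        d = GroupDistribution(10.0, 8.0, 13.0)
        assert implied_auc(d, d, "higher") == pytest.approx(0.5)

    def test_gfap_table_parameters(self):
        a = implied_auc(
            DEFAULT_BIOMARKER_DISTRIBUTIONS["gfap"]["negative"],
            DEFAULT_BIOMARKER_DISTRIBUTIONS["gfap"]["positive"],
            "higher",
        )
        assert a == pytest.approx(0.719, abs=0.001)

    def test_abeta_ipms_table_parameters(self):
        a = implied_auc(
            DEFAULT_BIOMARKER_DISTRIBUTIONS["abeta42_40_ipms"]["negative"],
            DEFAULT_BIOMARKER_DISTRIBUTIONS["abeta42_40_ipms"]["positive"],
            "lower",
        )
        assert a == pytest.approx(0.799, abs=0.001)

    def test_direction_flip_mirrors_auc(self):
        neg = GroupDistribution(10.0, 8.0, 13.0)
        pos = GroupDistribution(14.0, 11.0, 18.0)
        assert implied_auc(neg, pos, "higher") + implied_auc(
            neg, pos, "lower"
        ) == pytest.approx(1.0)


class TestGenerateCohort:
    def test_default_composition(self, default_cohort):
        c = default_cohort
        assert len(c) == 118
        assert (c["abeta_status"] == "positive").sum() == 60
        assert (c["abeta_status"] == "negative").sum() == 58
        by = c.groupby(["abeta_status", "diagnosis"]).size()
        assert by["negative", "CU"] == 30 and by["negative", "CI"] == 28
        assert by["positive", "CU"] == 20 and by["positive", "CI"] == 40
        # exact-count sex and APOE contingency
        assert c.groupby("abeta_status")["apoe_carrier"].sum().tolist() == [15, 32]
        assert (
            c.groupby("abeta_status")["sex"].apply(lambda s: (s == "F").sum()).tolist()
            == [24, 26]
        )

    def test_same_seed_identical(self):
        cfg = GeneratorConfig(seed=3)
        assert generate_cohort(cfg).equals(generate_cohort(cfg))

    def test_different_seed_differs(self):
        a = generate_cohort(GeneratorConfig(seed=3))
        b = generate_cohort(GeneratorConfig(seed=4))
        assert not a["gfap"].equals(b["gfap"])

    def test_suvr_consistent_with_status(self, default_cohort):
        pos = default_cohort["abeta_status"] == "positive"
        assert (default_cohort.loc[pos, "suvr"] > 1.11).all()
        assert (default_cohort.loc[~pos, "suvr"] <= 1.11).all()

    def test_validates_and_has_no_missing(self, default_cohort):
        validate_cohort(default_cohort)  # should not raise
        assert not default_cohort.isna().any().any()

    def test_marginals_converge_to_configured_quartiles(self, huge_cohort):
        """Empirical median and quartile ratio converge to the printed
        values; quartile endpoints converge to the fitted log-normal's
        (which reproduces asymmetric printed IQRs in ratio, not endpoint
        by endpoint — the cost of a two-parameter family)."""
        z75 = norm.ppf(0.75)
        for col in BIOMARKER_COLUMNS:
            for grp in ("negative", "positive"):
                d = DEFAULT_BIOMARKER_DISTRIBUTIONS[col][grp]
                mu, sigma = lognormal_params_from_quartiles(d)
                x = huge_cohort.loc[huge_cohort["abeta_status"] == grp, col]
                q25, med, q75 = np.percentile(x, [25, 50, 75])
                assert med == pytest.approx(d.median, rel=0.03)
                assert q75 / q25 == pytest.approx(d.q75 / d.q25, rel=0.03)
                assert q25 == pytest.approx(np.exp(mu - sigma * z75), rel=0.03)
                assert q75 == pytest.approx(np.exp(mu + sigma * z75), rel=0.03)

    def test_empirical_auc_matches_implied(self, huge_cohort):
        labels = abeta_binary(huge_cohort)
        for col in BIOMARKER_COLUMNS:
            d = DEFAULT_BIOMARKER_DISTRIBUTIONS[col]
            expected = implied_auc(
                d["negative"], d["positive"], BIOMARKERS[col].direction
            )
            got = auc(huge_cohort[col].to_numpy(), labels, BIOMARKERS[col].direction)
            assert got == pytest.approx(expected, abs=0.005)

    def test_normal_scores_correlation_matches_copula(self, large_cohort):
        cfg = GeneratorConfig()
        neg = large_cohort[large_cohort["abeta_status"] == "negative"]
        scores = {
            col: norm.ppf(neg[col].rank().to_numpy() / (len(neg) + 1))
            for col in BIOMARKER_COLUMNS
        }
        for a, b, target in [
            ("gfap", "ptau181", 0.4),
            ("abeta42_40_ipms", "abeta42_40_simoa", 0.6),
            ("gfap", "abeta42_40_ipms", -0.25),
        ]:
            r, _ = pearsonr(scores[a], scores[b])
            assert r == pytest.approx(
                cfg.copula_correlation.loc[a, b], abs=0.02
            )
            assert r == pytest.approx(target, abs=0.02)

    def test_non_positive_definite_copula_rejected(self):
        cfg = GeneratorConfig()
        bad = cfg.copula_correlation.copy()
        bad.loc["gfap", "ptau181"] = bad.loc["ptau181", "gfap"] = 0.999
        bad.loc["gfap", "nfl"] = bad.loc["nfl", "gfap"] = 0.999
        bad.loc["ptau181", "nfl"] = bad.loc["nfl", "ptau181"] = -0.999
        with pytest.raises(ValueError, match="positive-definite"):
            GeneratorConfig(copula_correlation=bad)

    def test_with_sizes_rescales_splits(self):
        cfg = GeneratorConfig().with_sizes(29, 30)
        assert cfg.cu_ci_split_by_group["negative"] == (15, 14)
        assert sum(cfg.cu_ci_split_by_group["positive"]) == 30
        c = generate_cohort(cfg)
        assert len(c) == 59
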