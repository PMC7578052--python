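"""Elastic-net predictor selection, debiased OLS refit and BH-FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from hepatex.association import (
    NONE_PREDICTOR,
    associate_all,
    association_frame,
    bh_fdr,
    debiased_fit,
    encode_predictors,
    fit_elastic_net,
)
from hepatex.io import CLINICAL_PREDICTORS


def random_clinical(n, rng):
    """A plausible random clinical table (13 predictors), no structure."""
    return pd.DataFrame(
        {
            "age_years": rng.normal(44, 10, n),
            "race": rng.choice(
                ["White", "Black", "Hispanic", "Asian", "Other"], n
            ),
            "sex": rng.choice(["M", "F"], n),
            "wbc": rng.lognormal(2.0, 0.3, n),
            "bun": rng.lognormal(2.6, 0.3, n),
            "creatinine": rng.lognormal(-0.1, 0.3, n),
            "total_bilirubin": rng.lognormal(0.5, 0.8, n),
            "albumin": rng.normal(3.5, 0.6, n),
            "ast": rng.lognormal(4.2, 0.8, n),
            "alt": rng.lognormal(3.5, 0.5, n),
            "platelet_count": rng.normal(200, 60, n),
            "meld": rng.normal(15, 6, n),
            "cirrhosis": rng.integers(0, 2, n),
        },
        index=[f"S{i}" for i in range(n)],
    )


class TestEncode:
    def test_one_hot_with_largest_reference(self):
        rng = np.random.default_rng(0)
        clin = random_clinical(60, rng)
        design, parent = encode_predictors(clin)
        # reference level of each categorical is dropped
        race_cols = [c for c in design.columns if c.startswith("race[")]
        assert len(race_cols) == clin["race"].nunique() - 1
        assert all(parent[c] == "race" for c in race_cols)
        sex_cols = [c for c in design.columns if c.startswith("sex[")]
        assert len(sex_cols) == 1

    def test_missing_predictor_rejected(self):
        rng = np.random.default_rng(1)
        clin = random_clinical(10, rng).drop(columns=["meld"])
        with pytest.raises(ValueError, match="meld"):
            encode_predictors(clin)


class TestElasticNet:
    def test_recovers_dominant_predictor(self):
        rng = np.random.default_rng(2)
        clin = random_clinical(80, rng)
        y = 2.0 * clin["ast"].to_numpy() + rng.normal(0, 1e-3, 80)
        fit = fit_elastic_net(y, clin, seed=0)
        assert fit.top_predictor == "ast"
        assert fit.elastic_rmse < 0.05 * np.std(y)

    def test_heavy_penalty_shrinks_to_none_sentinel(self):
        rng = np.random.default_rng(3)
        clin = random_clinical(50, rng)
        y = rng.normal(size=50)
        fit = fit_elastic_net(y, clin, seed=0, alphas=[1e6])
        assert fit.top_predictor == NONE_PREDICTOR
        assert fit.top_column is None

    def test_grouping_keeps_duplicated_signal_columns(self):
        # alt made an exact copy of ast: the l2 part of the penalty spreads
        # weight over both copies instead of picking one arbitrarily
        rng = np.random.default_rng(4)
        clin = random_clinical(80, rng)
        clin["alt"] = clin["ast"]
        y = 1.5 * clin["ast"].to_numpy() + rng.normal(0, 5.0, 80)
        fit = fit_elastic_net(y, clin, seed=0, l1_ratios=(0.5,))
        assert abs(fit.coefficients["ast"]) > 1e-8
        assert abs(fit.coefficients["alt"]) > 1e-8

    def test_top_predictor_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(5)
        clin = random_clinical(70, rng)
        y = 3.0 * clin["wbc"].to_numpy() + rng.normal(0, 1.0, 70)
        base = fit_elastic_net(y, clin, seed=1)
        scaled = clin.copy()
        scaled["wbc"] = scaled["wbc"] * 1000.0 + 7.5  # different units
        rescaled = fit_elastic_net(y, scaled, seed=1)
        assert base.top_predictor == rescaled.top_predictor == "wbc"


class TestDebiasedFit:
    def test_exact_linear_relation(self):
        x = np.arange(10.0)
        coef, p = debiased_fit(3.0 * x + 1.0, x)
        assert coef == pytest.approx(3.0)
        assert p < 1e-12

    def test_matches_ols_oracle(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(6)
        x = rng.normal(size=40)
        y = 0.7 * x + rng.normal(size=40)
        coef, p = debiased_fit(y, x)
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        assert coef == pytest.approx(ols.params[1], rel=1e-10)
        assert p == pytest.approx(ols.pvalues[1], rel=1e-8)

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(7)
        pvals = []
        for _ in range(500):
            x = rng.normal(size=200)
            y = rng.normal(size=200)
            pvals.append(debiased_fit(y, x)[1])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_sign_recovered_under_strong_signal(self):
        rng = np.random.default_rng(8)
        hits = 0
        for _ in range(100):
            x = rng.normal(size=50)
            y = -2.0 * x + rng.normal(size=50)
            hits += debiased_fit(y, x)[0] < 0
        assert hits >= 95

    def test_small_bias_of_debiased_estimate(self):
        rng = np.random.default_rng(9)
        beta = 1.7
        estimates = [
            debiased_fit(
                beta * x + rng.normal(size=200), x
            )[0]
            for x in (rng.normal(size=200) for _ in range(100))
        ]
        assert abs(np.mean(estimates) - beta) < 0.05 * beta

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError):
            debiased_fit(np.arange(5.0), np.ones(5))


class TestBHFDR:
    def test_hand_worked_step_up(self):
        out = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.37])[0] == pytest.approx(0.37)

    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30)
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_and_dominates_raw(self, ps):
        adj = bh_fdr(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-15)
        assert np.all(adj <= 1.0)
        order = np.argsort(ps, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)

    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30)
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_statsmodels_oracle(self, ps):
        from statsmodels.stats.multitest import multipletests

        ref = multipletests(ps, method="fdr_bh")[1]
        assert np.allclose(bh_fdr(ps), ref, atol=1e-12)

    def test_invariant_to_input_order(self):
        rng = np.random.default_rng(10)
        ps = rng.random(15)
        perm = rng.permutation(15)
        assert np.allclose(bh_fdr(ps)[perm], bh_fdr(ps[perm]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestAssociateAll:
    def _tables(self, rng, n=60):
        clin = random_clinical(n, rng)
        features = pd.DataFrame(
            {
                "0 GLNU": 2.0 * clin["wbc"] + rng.normal(0, 1, n),
                "45 RLN": -1.0 * clin["ast"] + rng.normal(0, 5, n),
                "Kurtosis": rng.normal(size=n),
                "LBM 3": rng.normal(size=n),
                "flat": np.ones(n),
            },
            index=clin.index,
        )
        return features, clin

    def test_one_record_per_feature_with_fdr_dominating(self):
        rng = np.random.default_rng(11)
        features, clin = self._tables(rng)
        records = associate_all(features, clin, seed=0)
        assert len(records) == 5
        for r in records:
            if r.testable:
                assert r.fdr_p >= r.p_value - 1e-15
                assert r.fdr_p <= 1.0
                assert r.top_predictor in CLINICAL_PREDICTORS

    def test_degenerate_feature_flagged_outside_family(self):
        rng = np.random.default_rng(12)
        features, clin = self._tables(rng)
        records = associate_all(features, clin, seed=0)
        flat = next(r for r in records if r.texture_feature == "flat")
        assert not flat.testable
        assert np.isnan(flat.p_value) and np.isnan(flat.fdr_p)
        # the BH family is exactly the testable records
        testable = [r for r in records if r.testable]
        ref = bh_fdr([r.p_value for r in testable])
        assert np.allclose([r.fdr_p for r in testable], ref)

    def test_records_in_manifest_order(self):
        rng = np.random.default_rng(13)
        features, clin = self._tables(rng)
        records = associate_all(features, clin, seed=0)
        named = [r.texture_feature for r in records]
        assert named.index("0 GLNU") < named.index("45 RLN")
        assert named.index("Kurtosis") < named.index("0 GLNU")

    def test_id_mismatch_rejected(self):
        rng = np.random.default_rng(14)
        features, clin = self._tables(rng)
        clin = clin.rename(index={"S0": "SX"})
        with pytest.raises(ValueError, match="id"):
            associate_all(features, clin, seed=0)

    def test_linked_predictors_recovered_with_signs(self):
        rng = np.random.default_rng(15)
        features, clin = self._tables(rng)
        records = {
            r.texture_feature: r
            for r in associate_all(features, clin, seed=0)
        }
        assert records["0 GLNU"].top_predictor == "wbc"
        assert records["0 GLNU"].linear_coefficient > 0
        assert records["45 RLN"].top_predictor == "ast"
        assert records["45 RLN"].linear_coefficient < 0

    def test_report_frame_columns(self):
        rng = np.random.default_rng(16)
        features, clin = self._tables(rng)
        df = association_frame(associate_all(features, clin, seed=0))
        assert list(df.columns) == [
            "texture_feature", "elastic_rmse", "top_predictor",
            "linear_coefficient", "p_value", "fdr_p",
        ]
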