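"""Codebook derivation tests: income scale, binning, dummies, trait scoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plandom.errors import DataError, DomainError
from plandom.recode import (
    DESIGN_COLUMNS,
    PREDICTOR_SETS,
    bin_risk,
    derive_table,
    equivalized_log_income,
    fit_one_factor,
    is_derived,
    score_trait_cfa,
    score_trait_mean,
)


class TestEquivalizedIncome:
    def test_family_of_four(self):
        # 2 adults + 2 children under 14 -> OECD scale 1 + 0.5 + 0.6 = 2.1
        assert equivalized_log_income(110_000, 2, 2) == pytest.approx(
            np.log(110_000 / 2.1))

    def test_single_adult_identity_scale(self):
        assert equivalized_log_income(np.exp(11.0), 1, 0) == pytest.approx(11.0)

    def test_nonpositive_income_rejected(self):
        with pytest.raises(DomainError):
            equivalized_log_income(0.0, 1, 0)
        with pytest.raises(DomainError):
            equivalized_log_income(50_000, 0, 0)


class TestRiskBinning:
    @pytest.mark.parametrize("raw,cat", [
        (0, 1), (1, 2), (2, 2), (3, 2), (4, 3), (5, 3),
        (6, 4), (7, 4), (8, 5), (9, 5), (10, 5),
    ])
    def test_full_domain_maps(self, raw, cat):
        assert bin_risk(raw) == cat

    def test_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            bin_risk(11)
        with pytest.raises(DomainError):
            bin_risk(-1)


class TestTraitMean:
    def test_plain_mean(self):
        assert score_trait_mean([5, 6, 7]) == pytest.approx(6.0)

    def test_reverse_keyed_middle_item(self):
        assert score_trait_mean([8, 2, 9], keying=[False, True, False]) == (
            pytest.approx((8 + 8 + 9) / 3))

    @given(st.floats(min_value=0, max_value=10, allow_nan=False))
    def test_constant_items_score_as_themselves(self, x):
        assert score_trait_mean([x, x, x]) == pytest.approx(x)

    def test_missing_item_rejected(self):
        with pytest.raises(DataError):
            score_trait_mean([1.0, np.nan, 3.0])


class TestTraitCfa:
    def test_recovers_generating_loadings(self):
        rng = np.random.default_rng(12)
        lam = np.array([0.8, 0.7, 0.6])
        f = rng.standard_normal(5000)
        items = lam * f[:, None] + np.sqrt(1 - lam**2) * rng.standard_normal((5000, 3))
        fit = fit_one_factor(items)
        assert fit.converged
        assert np.all(np.abs(fit.loadings - lam) < 0.05)
        scores, method = score_trait_cfa(items)
        assert method == "cfa"
        assert abs(np.corrcoef(scores, f)[0, 1]) > 0.85

    def test_collinear_items_fall_back_and_match_item_mean(self):
        rng = np.random.default_rng(3)
        base = rng.standard_normal(500)
        items = np.column_stack([base, base, base])
        with pytest.warns(UserWarning):
            scores, method = score_trait_cfa(items)
        mean = items.mean(axis=1)
        assert abs(np.corrcoef(scores, mean)[0, 1]) == pytest.approx(1.0)

    def test_noiseless_items_score_the_latent_exactly(self):
        rng = np.random.default_rng(4)
        lam = np.array([0.8, 0.7, 0.6])
        f = rng.standard_normal(400)
        items = lam * f[:, None]
        with pytest.warns(UserWarning):  # rank-1 correlations are a Heywood case
            scores, _ = score_trait_cfa(items)
        assert abs(np.corrcoef(scores, f)[0, 1]) == pytest.approx(1.0)

    def test_cfa_and_mean_scores_agree_on_unidimensional_items(self):
        rng = np.random.default_rng(5)
        lam = np.array([0.85, 0.75, 0.65])
        f = rng.standard_normal(3000)
        items = 5 + 2 * (lam * f[:, None]) + 0.8 * rng.standard_normal((3000, 3))
        scores, method = score_trait_cfa(items)
        assert method == "cfa"
        assert abs(np.corrcoef(scores, score_trait_mean(items))[0, 1]) >= 0.95

    def test_loadings_match_independent_ml_factor_analysis(self):
        """Closed-form one-factor ML agrees with an EM-based ML fitter on
        standardized items (up to sign)."""
        FactorAnalysis = pytest.importorskip(
            "sklearn.decomposition").FactorAnalysis
        rng = np.random.default_rng(21)
        lam = np.array([0.75, 0.65, 0.55])
        f = rng.standard_normal(4000)
        items = lam * f[:, None] + np.sqrt(1 - lam**2) * rng.standard_normal((4000, 3))
        fit = fit_one_factor(items)
        Z = (items - items.mean(0)) / items.std(0)
        ref = FactorAnalysis(n_components=1, tol=1e-6).fit(Z)
        ref_load = np.abs(ref.components_.ravel())
        assert np.all(np.abs(fit.loadings - ref_load) < 0.02)

    def test_zero_variance_item_rejected(self):
        items = np.column_stack([np.ones(100), np.random.default_rng(0).random(100),
                                 np.random.default_rng(1).random(100)])
        with pytest.raises(DataError):
            fit_one_factor(items)


class TestDeriveTable:
    def test_codebook_examples(self, survey_small):
        t = survey_small
        d = derive_table(t, scoring="mean")
        # good health = self-rated 1 or 2
        assert (d["good_health"].to_numpy() ==
                t["subjective_health"].isin([1, 2]).to_numpy()).all()
        # age 66 falls in the open-ended top group
        idx66 = t.index[t["age_years"] >= 66]
        assert (d.loc[idx66, "age_66plus"] == 1).all()
        # reference group carries no dummy
        ref = t.index[(t["age_years"] >= 26) & (t["age_years"] <= 35)]
        age_cols = [c for c in DESIGN_COLUMNS if c.startswith("age_")]
        assert (d.loc[ref, age_cols].sum(axis=1) == 0).all()

    def test_raw_deductible_recode(self):
        t = pd.DataFrame({"deductible": [300, 500, 1000, 1500, 2000, 2500]})
        # build a minimal raw table around it
        base = _tiny_raw(6)
        base["deductible"] = t["deductible"]
        d = derive_table(base, scoring="mean")
        assert d["voluntary_deductible"].tolist() == [0, 1, 1, 1, 1, 1]

    def test_dummy_blocks_sum_to_at_most_one(self, derived_small):
        for cols in PREDICTOR_SETS.values():
            block = derived_small[list(cols)]
            if set(np.unique(block)) <= {0.0, 1.0}:
                assert (block.sum(axis=1) <= 1).all()

    def test_rederivation_is_a_no_op(self, derived_small):
        again = derive_table(derived_small)
        pd.testing.assert_frame_equal(again, derived_small)
        assert is_derived(derived_small)

    def test_unmapped_code_error_names_row_and_column(self):
        base = _tiny_raw(60)
        base.loc[7, "education"] = 9
        with pytest.raises(DataError, match=r"education.*row 7"):
            derive_table(base, scoring="mean")

    def test_every_legal_raw_value_maps(self):
        """Sweep the full raw domains through derivation without error."""
        n = 264  # covers 26..110 ages, all codes, cyclically
        rng = np.random.default_rng(42)
        base = _tiny_raw(n)
        base["age_years"] = 26 + (np.arange(n) % 85)
        base["education"] = 1 + (np.arange(n) % 3)
        base["subjective_health"] = 1 + (np.arange(n) % 5)
        base["risk_raw"] = np.arange(n) % 11
        for col in ("female", "married", "urban", "chronic",
                    "doctor_visits", "hospital_stays"):
            base[col] = rng.integers(0, 2, n)
        d = derive_table(base, scoring="mean")
        # every row lands in exactly one risk category (dummy or reference)
        risk_cols = [f"risk_{k}" for k in (2, 3, 4, 5)]
        assert set(d[risk_cols].sum(axis=1).unique()) <= {0.0, 1.0}
        assert len(d) == n


def _tiny_raw(n: int) -> pd.DataFrame:
    """A small legal raw table with enough variation for trait scoring."""
    rng = np.random.default_rng(99)
    t = pd.DataFrame({
        "female": rng.integers(0, 2, n),
        "age_years": rng.integers(26, 90, n),
        "education": rng.integers(1, 4, n),
        "household_income": rng.lognormal(11.5, 0.4, n),
        "n_adults": rng.integers(1, 4, n),
        "n_children_under14": rng.integers(0, 3, n),
        "married": rng.integers(0, 2, n),
        "urban": rng.integers(0, 2, n),
        "subjective_health": rng.integers(1, 6, n),
        "chronic": rng.integers(0, 2, n),
        "doctor_visits": rng.integers(0, 2, n),
        "hospital_stays": rng.integers(0, 2, n),
        "risk_raw": rng.integers(0, 11, n),
    })
    for j in range(1, 16):
        t[f"bfi_item_{j}"] = rng.integers(0, 11, n)
    return t
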