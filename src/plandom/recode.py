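"""Variable derivation: from raw survey columns to the analysis design.

Implements the codebook of the Swiss health-plan choice analysis: binary
outcome coding (voluntary deductible, alternative/managed-care plan,
supplementary hospital insurance), five age groups, three education levels,
OECD-equivalized log income, a five-category risk-attitude recode of the
0-10 risk item, binary health indicators, and Big Five construct scores
from the 15-item inventory (one-factor CFA per trait, with a mean-score
fallback on non-convergence).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, DomainError

logger = logging.getLogger(__name__)

OUTCOMES = ("voluntary_deductible", "alternative_plan", "supplementary_insurance")

TRAITS = ("openness", "conscientiousness", "extraversion", "agreeableness", "neuroticism")

#: Design columns of the derived table, grouped into the 16 predictor sets
#: that dominance analysis treats as units of importance.
PREDICTOR_SETS: dict[str, tuple[str, ...]] = {
    "female": ("female",),
    "age_groups": ("age_36_45", "age_46_55", "age_56_65", "age_66plus"),
    "education": ("edu_intermediate", "edu_high"),
    "log_income": ("log_income",),
    "married": ("married",),
    "urban": ("urban",),
    "good_health": ("good_health",),
    "chronic": ("chronic",),
    "doctor_visits": ("doctor_visits",),
    "hospital_stays": ("hospital_stays",),
    "risk_attitude": ("risk_2", "risk_3", "risk_4", "risk_5"),
    "openness": ("openness",),
    "conscientiousness": ("conscientiousness",),
    "extraversion": ("extraversion",),
    "agreeableness": ("agreeableness",),
    "neuroticism": ("neuroticism",),
}

DESIGN_COLUMNS: tuple[str, ...] = tuple(
    c for cols in PREDICTOR_SETS.values() for c in cols
)


@dataclass(frozen=True)
class Codebook:
    """Coding rules mapping raw survey values to analysis variables.

    Defaults encode the published codebook: five age bands starting at 26,
    education in three levels, the CHF 300 standard deductible vs. the five
    voluntary levels, good health = self-rated 1-2 on the 1-5 scale, the
    modified OECD equivalence scale, and the trait-item assignment of the
    BFI-15 with its negatively keyed items.
    """

    age_edges: tuple[int, ...] = (26, 36, 46, 56, 66)
    age_labels: tuple[str, ...] = ("26_35", "36_45", "46_55", "56_65", "66plus")
    age_max: int = 110
    education_map: Mapping[int, str] = field(
        default_factory=lambda: {1: "low", 2: "intermediate", 3: "high"}
    )
    # raw 0-10 risk item -> five categories (1 averse ... 5 seeking)
    risk_bins: Mapping[int, int] = field(
        default_factory=lambda: {
            0: 1, 1: 2, 2: 2, 3: 2, 4: 3, 5: 3, 6: 4, 7: 4, 8: 5, 9: 5, 10: 5,
        }
    )
    health_good_values: frozenset = frozenset({1, 2})
    health_values: frozenset = frozenset({1, 2, 3, 4, 5})
    standard_deductible: int = 300
    voluntary_deductibles: frozenset = frozenset({500, 1000, 1500, 2000, 2500})
    oecd_first_adult: float = 1.0
    oecd_additional_person: float = 0.5   # each further household member aged 14+
    oecd_child_under14: float = 0.3
    trait_items: Mapping[str, tuple[int, int, int]] = field(
        default_factory=lambda: {
            "openness": (1, 2, 3),
            "conscientiousness": (4, 5, 6),
            "extraversion": (7, 8, 9),
            "agreeableness": (10, 11, 12),
            "neuroticism": (13, 14, 15),
        }
    )
    # "tends to be lazy", "is reserved", "is sometimes rude to others",
    # "remains calm in tense situations"
    reverse_keyed: frozenset = frozenset({5, 9, 10, 15})

    def oecd_scale(self, n_adults, n_children_under14):
        """Modified OECD equivalence scale for a household."""
        n_adults = np.asarray(n_adults)
        n_children = np.asarray(n_children_under14)
        return (
            self.oecd_first_adult
            + self.oecd_additional_person * (n_adults - 1)
            + self.oecd_child_under14 * n_children
        )


DEFAULT_CODEBOOK = Codebook()


def equivalized_log_income(household_income, n_adults, n_children_under14,
                           codebook: Codebook = DEFAULT_CODEBOOK):
    """Log of household income divided by the modified OECD scale.

    The first adult counts 1.0, each additional household member aged 14+
    counts 0.5, and each child under 14 counts 0.3.
    """
    income = np.asarray(household_income, dtype=float)
    n_adults_arr = np.asarray(n_adults)
    if np.any(income <= 0):
        raise DomainError("household_income must be strictly positive")
    if np.any(n_adults_arr < 1):
        raise DomainError("n_adults must be >= 1")
    scale = codebook.oecd_scale(n_adults_arr, n_children_under14)
    out = np.log(income / scale)
    return float(out) if out.ndim == 0 else out


def bin_risk(raw, codebook: Codebook = DEFAULT_CODEBOOK):
    """Collapse the 0-10 risk item into five categories.

    0 -> 1 (risk-averse), 1-3 -> 2, 4-5 -> 3 (risk-neutral), 6-7 -> 4,
    8-10 -> 5 (risk-seeking).
    """
    arr = np.asarray(raw)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    if not np.all(np.isin(arr, list(codebook.risk_bins))):
        bad = arr[~np.isin(arr, list(codebook.risk_bins))]
        raise DomainError(f"risk value(s) outside 0-10: {np.unique(bad).tolist()}")
    lut = np.zeros(11, dtype=int)
    for k, v in codebook.risk_bins.items():
        lut[k] = v
    out = lut[arr.astype(int)]
    return int(out[0]) if scalar else out


def score_trait_mean(items, keying: Sequence[bool] | None = None):
    """Average of three 0-10 items, flipping reverse-keyed items as 10 - x.

    ``keying`` marks reverse-keyed positions (True = reversed). Accepts a
    single (3,) triple or an (n, 3) matrix.
    """
    arr = np.asarray(items, dtype=float)
    scalar = arr.ndim == 1
    arr = np.atleast_2d(arr)
    if arr.shape[1] != 3:
        raise DataError(f"expected 3 items per trait, got {arr.shape[1]}")
    if np.any(~np.isfinite(arr)):
        raise DataError("missing or non-finite item value")
    if keying is not None:
        flip = np.asarray(keying, dtype=bool)
        arr = arr.copy()
        arr[:, flip] = 10.0 - arr[:, flip]
    out = arr.mean(axis=1)
    return float(out[0]) if scalar else out


@dataclass
class OneFactorFit:
    """A one-factor model for three standardized indicators.

    With three indicators the model is just-identified, so the maximum
    likelihood solution reproduces the sample correlations exactly and the
    loadings have the closed form lambda_1 = sqrt(r12*r13/r23) (and cyclic).
    The solution is admissible only when the three correlations share a
    consistent sign pattern and no loading exceeds 1 (Heywood case).
    """

    loadings: np.ndarray
    uniquenesses: np.ndarray
    converged: bool
    message: str = ""


def fit_one_factor(items: np.ndarray) -> OneFactorFit:
    """ML one-factor fit for an (n, 3) item matrix on the correlation scale."""
    X = np.asarray(items, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3:
        raise DataError("expected an (n, 3) item matrix")
    if X.shape[0] < 50:
        raise DataError("need n >= 50 observations for factor analysis")
    sd = X.std(axis=0)
    if np.any(sd <= 0):
        raise DataError(f"zero-variance item(s) at positions {np.flatnonzero(sd <= 0).tolist()}")
    R = np.corrcoef(X, rowvar=False)
    r12, r13, r23 = R[0, 1], R[0, 2], R[1, 2]
    prods = np.array([r12 * r13 / r23 if r23 != 0 else np.nan,
                      r12 * r23 / r13 if r13 != 0 else np.nan,
                      r13 * r23 / r12 if r12 != 0 else np.nan])
    if np.any(~np.isfinite(prods)) or np.any(prods <= 0):
        return OneFactorFit(np.full(3, np.nan), np.full(3, np.nan), False,
                            "inconsistent correlation signs; no admissible solution")
    lam = np.sqrt(prods)
    if np.any(lam >= 1.0):
        return OneFactorFit(lam, 1.0 - lam**2, False, "Heywood case: loading >= 1")
    return OneFactorFit(lam, 1.0 - lam**2, True)


def score_trait_cfa(items: np.ndarray, return_fit: bool = False):
    """Regression-method factor scores from a one-factor model of 3 items.

    Items must already be keyed in the positive direction. On an
    inadmissible/non-converged factor solution the function falls back to
    the item mean with a logged warning (the same pragmatic fallback the
    extraversion construct requires on the real survey).
    Returns ``(scores, method)`` or ``(scores, method, fit)``.
    """
    X = np.asarray(items, dtype=float)
    fit = fit_one_factor(X)
    if not fit.converged:
        logger.warning("one-factor model inadmissible (%s); falling back to mean score",
                       fit.message)
        warnings.warn(f"CFA fallback to mean score: {fit.message}", stacklevel=2)
        scores = score_trait_mean(X)
        method = "mean"
    else:
        Z = (X - X.mean(axis=0)) / X.std(axis=0)
        R = np.corrcoef(X, rowvar=False)
        w = np.linalg.solve(R, fit.loadings)
        scores = Z @ w
        method = "cfa"
    if return_fit:
        return scores, method, fit
    return scores, method


def is_derived(table: pd.DataFrame) -> bool:
    """True if the table already carries the derived design schema."""
    return set(DESIGN_COLUMNS).issubset(table.columns)


def _check_codes(series: pd.Series, valid, column: str):
    ok = series.isin(list(valid))
    if not ok.all():
        row = int(series.index[~ok][0])
        raise DataError(
            f"unmapped value {series.loc[row]!r} in column {column!r} at row {row}"
        )


def derive_table(table: pd.DataFrame, codebook: Codebook = DEFAULT_CODEBOOK,
                 scoring: str = "cfa") -> pd.DataFrame:
    """Build the analysis design from a raw survey table.

    Produces dummy-coded predictors for the 16 predictor sets with reference
    categories male / age 26-35 / low education / not married / rural /
    fair-poor health / risk category 1, plus trait construct scores
    (``scoring``: ``"cfa"`` or ``"mean"``) standardized to mean 0, sd 1 on
    the analysis sample. Outcome columns are passed through; a raw
    ``deductible`` column (CHF) is recoded to the binary voluntary indicator.
    Idempotent: a table that already has the derived schema is returned as a
    copy unchanged.
    """
    if scoring not in ("cfa", "mean"):
        raise ValueError(f"scoring must be 'cfa' or 'mean', got {scoring!r}")
    if is_derived(table):
        return table.copy()

    t = table.reset_index(drop=True)
    out = pd.DataFrame(index=t.index)

    required = ["female", "age_years", "education", "household_income", "n_adults",
                "n_children_under14", "married", "urban", "subjective_health",
                "chronic", "doctor_visits", "hospital_stays", "risk_raw"] + [
                    f"bfi_item_{j}" for j in range(1, 16)]
    missing = [c for c in required if c not in t.columns]
    if missing:
        raise DataError(f"missing raw columns: {missing}")

    for col in ("female", "married", "urban", "chronic", "doctor_visits", "hospital_stays"):
        _check_codes(t[col], {0, 1}, col)
        out[col if col != "female" else "female"] = t[col].astype(float)
    out["female"] = t["female"].astype(float)

    # age groups
    age = t["age_years"]
    if (age < codebook.age_edges[0]).any() or (age > codebook.age_max).any():
        row = int(age.index[(age < codebook.age_edges[0]) | (age > codebook.age_max)][0])
        raise DataError(f"unmapped value {age.loc[row]!r} in column 'age_years' at row {row}")
    edges = list(codebook.age_edges) + [codebook.age_max + 1]
    group = pd.cut(age, bins=edges, labels=codebook.age_labels, right=False)
    for lab in codebook.age_labels[1:]:
        out[f"age_{lab}"] = (group == lab).astype(float)

    # education (reference: low)
    _check_codes(t["education"], codebook.education_map.keys(), "education")
    level = t["education"].map(codebook.education_map)
    out["edu_intermediate"] = (level == "intermediate").astype(float)
    out["edu_high"] = (level == "high").astype(float)

    out["log_income"] = equivalized_log_income(
        t["household_income"].to_numpy(), t["n_adults"].to_numpy(),
        t["n_children_under14"].to_numpy(), codebook)

    _check_codes(t["subjective_health"], codebook.health_values, "subjective_health")
    out["good_health"] = t["subjective_health"].isin(codebook.health_good_values).astype(float)

    risk_cat = bin_risk(t["risk_raw"].to_numpy(), codebook)
    for k in (2, 3, 4, 5):
        out[f"risk_{k}"] = (risk_cat == k).astype(float)

    # trait constructs: re-key reversed items, score, standardize per sample
    scoring_used = {}
    for trait in TRAITS:
        ids = codebook.trait_items[trait]
        items = t[[f"bfi_item_{j}" for j in ids]].to_numpy(dtype=float)
        items = items.copy()
        for pos, j in enumerate(ids):
            if j in codebook.reverse_keyed:
                items[:, pos] = 10.0 - items[:, pos]
        if scoring == "mean":
            scores = score_trait_mean(items)
            scoring_used[trait] = "mean"
        else:
            scores, method = score_trait_cfa(items)
            scoring_used[trait] = method
        sd = scores.std()
        if sd <= 0:
            raise DataError(f"degenerate trait scores for {trait}")
        out[trait] = (scores - scores.mean()) / sd

    # outcomes: pass-through, plus raw deductible recode if present
    if "deductible" in t.columns:
        valid = codebook.voluntary_deductibles | {codebook.standard_deductible}
        _check_codes(t["deductible"], valid, "deductible")
        out["voluntary_deductible"] = t["deductible"].isin(
            codebook.voluntary_deductibles).astype(float)
    for oc in OUTCOMES:
        if oc in t.columns and oc not in out.columns:
            _check_codes(t[oc], {0, 1}, oc)
            out[oc] = t[oc].astype(float)

    out = out[[c for c in DESIGN_COLUMNS if c in out.columns]
              + [c for c in OUTCOMES if c in out.columns]]
    out.attrs["scoring"] = scoring_used
    return out
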