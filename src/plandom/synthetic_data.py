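"""Synthetic survey generator emulating the Swiss health-plan choice data.

Continuous latent variables (income, risk propensity, the five traits, a
health liability, and education propensity) are drawn from a Gaussian
copula; discrete covariates are produced by thresholding the latents at
quantiles matching configurable marginal shares; BFI items load on their
trait latent with additive noise; and the three binary plan-choice outcomes
are drawn from logistic models with configurable coefficients on the
derived-predictor scale.

Every column draws from its own counter-based substream of the master seed,
so adding a column never perturbs previously generated ones.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit
from scipy.stats import norm

from . import recode
from .errors import ConfigError

LATENT_NAMES = (
    "income", "risk", "openness", "conscientiousness", "extraversion",
    "agreeableness", "neuroticism", "health", "education",
)


def default_latent_corr() -> pd.DataFrame:
    """Placeholder latent correlation matrix (the survey's joint covariate
    law is not public; only marginal shares are). Income-education and
    risk-trait entries follow the usual signs in the risk-preference
    literature."""
    R = pd.DataFrame(np.eye(len(LATENT_NAMES)), index=LATENT_NAMES, columns=LATENT_NAMES)

    def set_(a, b, v):
        R.loc[a, b] = v
        R.loc[b, a] = v

    set_("income", "education", 0.45)
    set_("income", "health", -0.15)
    set_("income", "risk", 0.10)
    set_("risk", "extraversion", 0.25)
    set_("risk", "openness", 0.20)
    set_("risk", "neuroticism", -0.25)
    set_("risk", "conscientiousness", -0.10)
    set_("risk", "agreeableness", -0.10)
    set_("health", "neuroticism", 0.20)
    set_("health", "conscientiousness", -0.10)
    set_("openness", "extraversion", 0.20)
    set_("openness", "agreeableness", 0.10)
    set_("conscientiousness", "agreeableness", 0.15)
    set_("extraversion", "agreeableness", 0.15)
    set_("neuroticism", "extraversion", -0.15)
    set_("education", "openness", 0.15)
    return R


#: Marginal category shares, set near the published pooled descriptives
#: (~55% female, ~62% married, ~73% urban, ...). Config, not constants.
DEFAULT_MARGINS: dict = {
    "female": 0.55,
    "married": 0.62,
    "urban": 0.73,
    "age_group_shares": (0.12, 0.14, 0.23, 0.21, 0.30),
    "age_group_bounds": ((26, 35), (36, 45), (46, 55), (56, 65), (66, 95)),
    "education_shares": (0.125, 0.54, 0.335),           # low / intermediate / high
    "risk_raw_shares": (0.07, 0.04, 0.05, 0.065, 0.15, 0.18,
                        0.16, 0.12, 0.08, 0.05, 0.035),  # items 0..10
    "subjective_health_shares": (0.35, 0.49, 0.10, 0.045, 0.015),
    "chronic": 0.39,
    "doctor_visits": 0.77,
    "hospital_stays": 0.16,
    # weight of the health-liability latent in each health indicator
    "health_mixing": {"chronic": 0.6, "doctor_visits": 0.5, "hospital_stays": 0.5},
    "n_adults_shares": {1: 0.25, 2: 0.60, 3: 0.10, 4: 0.05},
    "n_children_shares": {0: 0.60, 1: 0.17, 2: 0.17, 3: 0.06},
}

#: Generative log-odds coefficients on the derived-predictor scale (traits
#: standardized). Directions follow the published odds-ratio patterns, e.g.
#: OR 0.76 for women on the voluntary-deductible choice, income OR 3.64 and
#: age-66+ OR 5.15 on supplementary insurance; risk attitude and the traits
#: carry the per-SD weight that makes them the leading predictors.
DEFAULT_COEFS: dict[str, dict[str, float]] = {
    "voluntary_deductible": {
        "female": float(np.log(0.76)),
        "age_36_45": -0.30, "age_46_55": -0.50, "age_56_65": -0.70, "age_66plus": -1.00,
        "edu_intermediate": 0.15, "edu_high": 0.30,
        "log_income": 0.80,
        "married": 0.00, "urban": -0.05,
        "good_health": 0.50, "chronic": -0.45,
        "doctor_visits": -0.50, "hospital_stays": -0.30,
        "risk_2": 0.25, "risk_3": 0.50, "risk_4": 0.80, "risk_5": 1.00,
        "openness": -0.55, "conscientiousness": 0.55, "extraversion": 0.50,
        "agreeableness": 0.50, "neuroticism": -0.55,
    },
    "alternative_plan": {
        "female": 0.00,
        "age_36_45": -0.05, "age_46_55": -0.10, "age_56_65": -0.35, "age_66plus": -0.50,
        "edu_intermediate": 0.20, "edu_high": 0.00,
        "log_income": -0.50,
        "married": 0.25, "urban": -0.25,
        "good_health": 0.10, "chronic": -0.10,
        "doctor_visits": -0.05, "hospital_stays": 0.00,
        "risk_2": 0.30, "risk_3": 0.55, "risk_4": 0.80, "risk_5": 0.90,
        "openness": 0.50, "conscientiousness": 0.50, "extraversion": 0.55,
        "agreeableness": 0.50, "neuroticism": -0.60,
    },
    "supplementary_insurance": {
        "female": 0.10,
        "age_36_45": 0.30, "age_46_55": 0.70, "age_56_65": 1.10,
        "age_66plus": float(np.log(5.15)),
        "edu_intermediate": 0.20, "edu_high": 0.50,
        "log_income": float(np.log(3.64)),
        "married": 0.15, "urban": 0.20,
        "good_health": 0.00, "chronic": 0.05,
        "doctor_visits": 0.35, "hospital_stays": 0.15,
        "risk_2": 0.30, "risk_3": 0.50, "risk_4": 0.70, "risk_5": 0.80,
        "openness": 0.50, "conscientiousness": 0.50, "extraversion": -0.45,
        "agreeableness": 0.50, "neuroticism": 0.50,
    },
}

#: Intercepts placing outcome prevalences near the published pooled uptake
#: shares (voluntary deductible ~0.61, alternative plan ~0.65,
#: supplementary insurance ~0.35).
DEFAULT_INTERCEPTS: dict[str, float] = {
    "voluntary_deductible": -8.10,
    "alternative_plan": 5.78,
    "supplementary_insurance": -17.49,
}


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic survey."""

    n_respondents: int = 3000
    seed: int = 0
    latent_names: tuple = LATENT_NAMES
    latent_corr: pd.DataFrame = field(default_factory=default_latent_corr)
    loadings: Mapping[str, tuple] = field(default_factory=lambda: {
        t: (0.8, 0.7, 0.6) for t in recode.TRAITS})
    item_noise_sd: float = 0.6
    item_center: float = 5.5
    item_spread: float = 2.0
    margins: dict = field(default_factory=lambda: dict(DEFAULT_MARGINS))
    income_log_mean: float = 11.6
    income_log_sd: float = 0.5
    outcome_coefs: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COEFS.items()})
    intercepts: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INTERCEPTS))
    reverse_keyed: frozenset = frozenset({5, 9, 10, 15})

    def validate(self) -> None:
        if self.n_respondents < 1:
            raise ConfigError("n_respondents must be >= 1")
        R = np.asarray(self.latent_corr, dtype=float)
        k = len(self.latent_names)
        if R.shape != (k, k):
            raise ConfigError(f"latent_corr must be {k}x{k}")
        if not np.allclose(R, R.T, atol=1e-12):
            raise ConfigError("latent_corr must be symmetric")
        if not np.allclose(np.diag(R), 1.0, atol=1e-12):
            raise ConfigError("latent_corr must have unit diagonal")
        try:
            np.linalg.cholesky(R)
        except np.linalg.LinAlgError:
            raise ConfigError("latent_corr is not positive definite") from None
        for t, lam in self.loadings.items():
            lam = np.asarray(lam, dtype=float)
            if lam.shape != (3,) or np.any(lam < 0) or np.any(lam > 1):
                raise ConfigError(f"loadings for {t!r} must be 3 values in [0, 1]")
        if self.item_noise_sd < 0:
            raise ConfigError("item_noise_sd must be nonnegative")

    # ---- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["latent_corr"] = np.asarray(self.latent_corr).tolist()
        d["latent_names"] = list(self.latent_names)
        d["loadings"] = {k: list(v) for k, v in self.loadings.items()}
        d["reverse_keyed"] = sorted(self.reverse_keyed)
        d["margins"] = _margins_to_plain(self.margins)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        names = tuple(d.get("latent_names", LATENT_NAMES))
        if "latent_corr" in d:
            d["latent_corr"] = pd.DataFrame(
                np.asarray(d["latent_corr"], dtype=float), index=names, columns=names)
        if "reverse_keyed" in d:
            d["reverse_keyed"] = frozenset(d["reverse_keyed"])
        if "margins" in d:
            d["margins"] = _margins_from_plain(d["margins"])
        d["latent_names"] = names
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _margins_to_plain(m: dict) -> dict:
    out = {}
    for k, v in m.items():
        if isinstance(v, tuple):
            v = [list(x) if isinstance(x, tuple) else x for x in v]
        if isinstance(v, dict):
            v = {int(a) if isinstance(a, (int, np.integer)) else a: b for a, b in v.items()}
        out[k] = v
    return out


def _margins_from_plain(m: dict) -> dict:
    out = dict(DEFAULT_MARGINS)
    for k, v in m.items():
        if isinstance(v, list):
            v = tuple(tuple(x) if isinstance(x, list) else x for x in v)
        if isinstance(v, dict) and k.startswith("n_"):
            v = {int(a): b for a, b in v.items()}  # YAML may stringify keys
        out[k] = v
    return out


def _rng(seed: int, name: str) -> np.random.Generator:
    """Substream keyed by (seed, crc32(name)): stable under column addition."""
    key = zlib.crc32(name.encode("utf8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


def _categorical_from_latent(z: np.ndarray, shares) -> np.ndarray:
    """Threshold a standard-normal latent at the quantiles of ``shares``;
    returns integer categories 0..k-1."""
    cuts = norm.ppf(np.cumsum(shares)[:-1] / np.sum(shares))
    return np.searchsorted(cuts, z, side="right")


def _binary_mixed(z: np.ndarray, share: float, weight: float, eps: np.ndarray) -> np.ndarray:
    u = weight * z + np.sqrt(1.0 - weight**2) * eps
    return (u > norm.ppf(1.0 - share)).astype(int)


def generate_covariates(config: GeneratorConfig) -> pd.DataFrame:
    """Draw a raw survey table (all columns except the outcomes)."""
    config.validate()
    n, seed = config.n_respondents, config.seed
    m = config.margins

    # correlated latents: per-latent base normals mixed through the Cholesky
    # factor, so appending a latent leaves earlier ones untouched
    names = list(config.latent_names)
    L = np.linalg.cholesky(np.asarray(config.latent_corr, dtype=float))
    E = np.column_stack([_rng(seed, f"latent_{nm}").standard_normal(n) for nm in names])
    Z = E @ L.T
    lat = {nm: Z[:, i] for i, nm in enumerate(names)}

    t = pd.DataFrame(index=pd.RangeIndex(n))
    t["female"] = (_rng(seed, "female").random(n) < m["female"]).astype(int)

    age_cat = _rng(seed, "age_group").choice(
        len(m["age_group_shares"]), size=n, p=np.asarray(m["age_group_shares"]) / np.sum(m["age_group_shares"]))
    lo = np.array([b[0] for b in m["age_group_bounds"]])
    hi = np.array([b[1] for b in m["age_group_bounds"]])
    width = hi - lo + 1
    u = _rng(seed, "age_within").random(n)
    t["age_years"] = lo[age_cat] + np.floor(u * width[age_cat]).astype(int)

    t["education"] = _categorical_from_latent(lat["education"], m["education_shares"]) + 1
    t["household_income"] = np.exp(config.income_log_mean
                                   + config.income_log_sd * lat["income"])

    ad_keys = np.array(sorted(m["n_adults_shares"]))
    ad_p = np.array([m["n_adults_shares"][k] for k in ad_keys], dtype=float)
    t["n_adults"] = _rng(seed, "n_adults").choice(ad_keys, size=n, p=ad_p / ad_p.sum())
    ch_keys = np.array(sorted(m["n_children_shares"]))
    ch_p = np.array([m["n_children_shares"][k] for k in ch_keys], dtype=float)
    t["n_children_under14"] = _rng(seed, "n_children").choice(
        ch_keys, size=n, p=ch_p / ch_p.sum())

    t["married"] = (_rng(seed, "married").random(n) < m["married"]).astype(int)
    t["urban"] = (_rng(seed, "urban").random(n) < m["urban"]).astype(int)

    t["subjective_health"] = _categorical_from_latent(
        -lat["health"], m["subjective_health_shares"]) + 1  # low liability -> good health
    for col in ("chronic", "doctor_visits", "hospital_stays"):
        eps = _rng(seed, f"{col}_noise").standard_normal(n)
        t[col] = _binary_mixed(lat["health"], m[col], m["health_mixing"][col], eps)

    t["risk_raw"] = _categorical_from_latent(lat["risk"], m["risk_raw_shares"])

    # BFI items: loading * trait latent + noise, affinely mapped to 0-10,
    # rounded to the 11-point response scale and clipped; reverse-keyed
    # items are stored flipped (10 - value), as answered on the survey
    for trait, ids in recode.DEFAULT_CODEBOOK.trait_items.items():
        lam = np.asarray(config.loadings[trait], dtype=float)
        for pos, j in enumerate(ids):
            eps = _rng(seed, f"bfi_item_{j}_noise").standard_normal(n)
            raw = lam[pos] * lat[trait] + config.item_noise_sd * eps
            val = config.item_center + config.item_spread * raw
            val = np.clip(np.round(val), 0, 10).astype(int)
            if j in config.reverse_keyed:
                val = 10 - val
            t[f"bfi_item_{j}"] = val
    return t


def generate_outcomes(table: pd.DataFrame, config: GeneratorConfig) -> pd.DataFrame:
    """Attach the three binary outcomes drawn from logistic models.

    The derived design is computed internally (mean-scored traits, which are
    deterministic), then each outcome is Bernoulli(logistic(a + x.b)) with
    its own seed substream.
    """
    config.validate()
    derived = recode.derive_table(table, scoring="mean")
    out = table.copy()
    for oc, coefs in config.outcome_coefs.items():
        unknown = set(coefs) - set(recode.DESIGN_COLUMNS)
        if unknown:
            raise ConfigError(f"unknown design terms for {oc!r}: {sorted(unknown)}")
        eta = np.full(len(derived), float(config.intercepts[oc]))
        for term, b in coefs.items():
            eta += b * derived[term].to_numpy()
        p = expit(eta)
        u = _rng(config.seed, f"outcome_{oc}").random(len(p))
        out[oc] = (u < p).astype(int)
        out.attrs.setdefault("outcome_mean_probability", {})[oc] = float(p.mean())
    return out


def generate_survey(config: GeneratorConfig) -> pd.DataFrame:
    """Covariates plus outcomes in one call."""
    return generate_outcomes(generate_covariates(config), config)


def write_csv(table: pd.DataFrame, path) -> None:
    """RFC-4180 CSV with header, stable formatting."""
    table.to_csv(path, index=False, lineterminator="\r\n")
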