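"""Dominance analysis over predictor sets for logistic outcomes.

Predictor importance is decomposed by fitting the outcome on every subset
of the p predictor sets (2^p logistic fits, memoized in a lattice keyed by
bitmask) and averaging each set's additional McFadden-R2 contribution:

* conditional dominance: average contribution at each model size k,
* general dominance: mean of the conditional values across sizes — the
  Shapley share of the full-model R2,
* complete dominance: one set beats another in every shared subset model.

Importance is attributed to predictor *sets* (e.g. the four age-group
dummies count as one unit), mirroring how categorical blocks are ranked in
applied work.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, SeparationError
from .models import _newton, null_loglik

logger = logging.getLogger(__name__)

RESCUE_RIDGE = 1e-6
STRICT_TOL = 1e-10  # strictness margin for complete-dominance comparisons


@dataclass(frozen=True)
class PredictorSet:
    """A named block of design columns treated as one unit of importance."""

    name: str
    columns: tuple[str, ...]

    def __post_init__(self):
        if len(self.columns) < 1:
            raise ValueError(f"predictor set {self.name!r} has no columns")


def default_predictor_sets(available: set[str] | None = None) -> list[PredictorSet]:
    """The 16 canonical sets of the plan-choice analysis (optionally
    restricted to columns present in a given table)."""
    from .recode import PREDICTOR_SETS

    out = []
    for name, cols in PREDICTOR_SETS.items():
        if available is None or set(cols).issubset(available):
            out.append(PredictorSet(name, tuple(cols)))
    return out


@dataclass
class SubsetLattice:
    """McFadden R2 for every subset of predictor sets, keyed by bitmask."""

    sets: list[PredictorSet]
    r2: np.ndarray               # length 2^p; NaN where the fit failed
    ok: np.ndarray               # bool flags per subset
    outcome: str
    n_obs: int
    rescued: int = 0             # subsets that needed the ridge rescue

    @property
    def p(self) -> int:
        return len(self.sets)

    def r2_of(self, subset) -> float:
        """R2 of a subset given by set names (any iterable)."""
        return float(self.r2[self._mask(subset)])

    def _mask(self, subset) -> int:
        idx = {s.name: i for i, s in enumerate(self.sets)}
        mask = 0
        for name in subset:
            mask |= 1 << idx[name]
        return mask


def build_lattice(derived: pd.DataFrame, outcome: str,
                  sets: list[PredictorSet] | None = None) -> SubsetLattice:
    """Fit the outcome on all 2^p subsets of predictor sets.

    All fits use the identical complete-case sample, fixed once, so the R2
    values are comparable across subsets. Each subset is fit exactly once.
    Failed fits are retried with a tiny ridge, then flagged; more than 1%
    flagged subsets aborts.
    """
    if sets is None:
        sets = default_predictor_sets(set(derived.columns))
    p = len(sets)
    if p > 20:
        raise ValueError(f"p={p} predictor sets exceed the hard cap of 20 (2^p fits)")
    names = [s.name for s in sets]
    if len(set(names)) != p:
        raise ValueError("predictor set names must be unique")
    allcols = [c for s in sets for c in s.columns]
    if len(set(allcols)) != len(allcols):
        raise ValueError("predictor sets must be disjoint")
    missing = [c for c in allcols if c not in derived.columns]
    if missing:
        raise DataError(f"design columns not in table: {missing}")
    if outcome not in derived.columns:
        raise DataError(f"outcome {outcome!r} not in table")

    sub = derived[allcols + [outcome]].dropna()
    y = sub[outcome].to_numpy(dtype=float)
    if y.size == 0 or y.min() == y.max():
        raise DataError(f"outcome {outcome!r} has a single class on the analysis sample")
    n = y.size
    X_all = np.column_stack([np.ones(n)] + [sub[c].to_numpy(dtype=float) for c in allcols])
    # column indices (into X_all) per set; 0 is the intercept
    col_idx: list[np.ndarray] = []
    start = 1
    for s in sets:
        col_idx.append(np.arange(start, start + len(s.columns)))
        start += len(s.columns)

    ll0 = null_loglik(y)
    p_bar = y.mean()
    size = 1 << p
    r2 = np.empty(size)
    ok = np.ones(size, dtype=bool)
    rescued = 0
    r2[0] = 0.0
    # warm-start store: fitted beta per mask (parent = mask minus lowest bit)
    betas: list[np.ndarray | None] = [None] * size
    betas[0] = np.array([np.log(p_bar / (1.0 - p_bar))])
    for mask in range(1, size):
        idx = [0]
        m = mask
        while m:
            i = (m & -m).bit_length() - 1
            idx.extend(col_idx[i])
            m &= m - 1
        X = X_all[:, idx]
        parent = mask & (mask - 1)
        low = (mask & -mask).bit_length() - 1
        b_par = betas[parent]
        beta0 = None
        if b_par is not None:
            nlow = len(col_idx[low])
            beta0 = np.concatenate([b_par[:1], np.zeros(nlow), b_par[1:]])
        try:
            beta, ll, _, converged, _ = _newton(X, y, beta0=beta0)
            if not converged:
                raise SeparationError([], "no convergence")
        except (SeparationError, np.linalg.LinAlgError):
            try:
                beta, ll, _, converged, _ = _newton(X, y, ridge=RESCUE_RIDGE)
                rescued += 1
                logger.info("subset %d rescued with ridge %g", mask, RESCUE_RIDGE)
                if not converged:
                    raise SeparationError([], "no convergence")
            except (SeparationError, np.linalg.LinAlgError):
                ok[mask] = False
                r2[mask] = np.nan
                continue
        betas[mask] = beta
        r2[mask] = 1.0 - ll / ll0

    n_failed = int((~ok).sum())
    if n_failed > 0.01 * size:
        raise RuntimeError(
            f"{n_failed}/{size} subset fits failed for outcome {outcome!r}; "
            f"first failures at masks {np.flatnonzero(~ok)[:5].tolist()}")
    if n_failed:
        warnings.warn(f"{n_failed} subset fit(s) failed and are flagged missing",
                      stacklevel=2)
    return SubsetLattice(sets=list(sets), r2=r2, ok=ok, outcome=outcome,
                         n_obs=n, rescued=rescued)


def additional_contribution(lattice: SubsetLattice, subset, j: str) -> float:
    """R2(S + {j}) - R2(S): the extra fit j brings on top of subset S."""
    subset = list(subset)
    if j in subset:
        raise ValueError(f"set {j!r} already in the subset")
    return lattice.r2_of(subset + [j]) - lattice.r2_of(subset)


def conditional_dominance(lattice: SubsetLattice) -> pd.DataFrame:
    """Average additional contribution of each set at each model size.

    Returns a (set x level) frame; level k averages over all C(p-1, k)
    subsets of size k that exclude the set. Failed subsets reduce the
    averaging denominator with a warning.
    """
    p = lattice.p
    masks = np.arange(1 << p)
    popcnt = np.array([bin(m).count("1") for m in masks])
    C = np.zeros((p, p))
    had_missing = False
    for j in range(p):
        bj = 1 << j
        sel = masks[(masks & bj) == 0]
        deltas = lattice.r2[sel | bj] - lattice.r2[sel]
        ks = popcnt[sel]
        valid = np.isfinite(deltas)
        if not valid.all():
            had_missing = True
        sums = np.bincount(ks[valid], weights=deltas[valid], minlength=p)
        cnts = np.bincount(ks[valid], minlength=p)
        with np.errstate(invalid="ignore"):
            C[j] = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
    if had_missing:
        warnings.warn("failed subsets excluded from conditional averages",
                      stacklevel=2)
    return pd.DataFrame(C, index=[s.name for s in lattice.sets],
                        columns=[f"level_{k}" for k in range(p)])


def general_dominance(conditional: pd.DataFrame) -> pd.Series:
    """Mean of the conditional values across levels: the Shapley weights."""
    return conditional.mean(axis=1)


def complete_dominance(lattice: SubsetLattice) -> pd.DataFrame:
    """Pairwise relation: 'dominates' iff i's contribution strictly exceeds
    j's in every subset containing neither (margin 1e-10); 'dominated' for
    the reverse; 'undetermined' otherwise (including the diagonal)."""
    p = lattice.p
    names = [s.name for s in lattice.sets]
    masks = np.arange(1 << p)
    D = pd.DataFrame("undetermined", index=names, columns=names)
    for i in range(p):
        bi = 1 << i
        for j in range(i + 1, p):
            bj = 1 << j
            sel = masks[(masks & (bi | bj)) == 0]
            di = lattice.r2[sel | bi] - lattice.r2[sel]
            dj = lattice.r2[sel | bj] - lattice.r2[sel]
            valid = np.isfinite(di) & np.isfinite(dj)
            di, dj = di[valid], dj[valid]
            if di.size and np.all(di > dj + STRICT_TOL):
                D.iloc[i, j], D.iloc[j, i] = "dominates", "dominated"
            elif di.size and np.all(dj > di + STRICT_TOL):
                D.iloc[i, j], D.iloc[j, i] = "dominated", "dominates"
    return D


def rank_predictors(general: pd.Series, top_k: int = 6,
                    decimals: int = 3) -> pd.Series:
    """Dense ranking of general-dominance weights at printed precision.

    Weights are rounded to ``decimals`` (3, the precision of published
    tables); the largest distinct rounded value gets rank 1, ties share a
    rank, and only the ``top_k`` largest distinct values receive a rank —
    the rest are left blank (<NA>).
    """
    g = np.asarray(general, dtype=float)
    if np.any(~np.isfinite(g)):
        raise ValueError("general dominance weights must be finite")
    r = np.round(g, decimals)
    distinct = np.sort(np.unique(r))[::-1]
    rank_of = {v: k + 1 for k, v in enumerate(distinct)}
    ranks = pd.Series(
        [rank_of[v] if rank_of[v] <= top_k else pd.NA for v in r],
        index=general.index if isinstance(general, pd.Series) else None,
        dtype="Int64")
    return ranks


@dataclass
class DominanceResult:
    """Full dominance decomposition for one outcome."""

    outcome: str
    sets: list[str]
    r2_full: float
    conditional: pd.DataFrame
    general: pd.Series           # raw weights, summing to r2_full
    percent: pd.Series           # weights as % of r2_full
    complete: pd.DataFrame
    ranking: pd.Series
    n_obs: int = 0
    lattice: SubsetLattice | None = field(default=None, repr=False)

    def table(self) -> pd.DataFrame:
        """Tidy general-dominance table: set, weight, percent, rank."""
        return pd.DataFrame({
            "set": self.sets,
            "weight": self.general.to_numpy(),
            "percent": self.percent.to_numpy(),
            "rank": self.ranking.to_numpy(),
        })


def dominance_analysis(derived: pd.DataFrame, outcome: str,
                       sets: list[PredictorSet] | None = None,
                       top_k: int = 6, keep_lattice: bool = False) -> DominanceResult:
    """End-to-end dominance analysis of one outcome."""
    lattice = build_lattice(derived, outcome, sets)
    cond = conditional_dominance(lattice)
    gen = general_dominance(cond)
    comp = complete_dominance(lattice)
    r2_full = float(lattice.r2[-1])
    percent = 100.0 * gen / r2_full if r2_full > 0 else gen * np.nan
    return DominanceResult(
        outcome=outcome, sets=[s.name for s in lattice.sets], r2_full=r2_full,
        conditional=cond, general=gen, percent=percent, complete=comp,
        ranking=rank_predictors(gen, top_k=top_k), n_obs=lattice.n_obs,
        lattice=lattice if keep_lattice else None,
    )
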