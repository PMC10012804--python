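"""Shared helpers and independent oracles for the test suite.

The oracles here deliberately avoid the code paths they check: subset fits
are recomputed from scratch with the public fitting API, Shapley values are
enumerated over orderings, and conditional/complete dominance are rebuilt
by explicit loops over subsets.
"""

from __future__ import annotations

from itertools import combinations, permutations

import numpy as np
import pandas as pd

from plandom.dominance import PredictorSet
from plandom.models import fit_logistic, mcfadden_r2


def random_instance(seed: int, p: int, n: int = 300, max_cols: int = 2):
    """A random logistic problem with p predictor sets of 1..max_cols columns."""
    rng = np.random.default_rng(seed)
    sets = []
    cols = []
    for i in range(p):
        k = int(rng.integers(1, max_cols + 1))
        names = tuple(f"s{i}_c{j}" for j in range(k))
        sets.append(PredictorSet(f"set{i}", names))
        cols.extend(names)
    # correlated design so contributions interact across subsets
    A = rng.normal(size=(len(cols), len(cols)))
    cov = A @ A.T + len(cols) * np.eye(len(cols))
    d = np.sqrt(np.diag(cov))
    corr = cov / np.outer(d, d)
    X = rng.multivariate_normal(np.zeros(len(cols)), corr, size=n)
    beta = rng.normal(scale=0.8, size=len(cols))
    eta = X @ beta + rng.normal(scale=0.2)
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    if y.min() == y.max():  # avoid degenerate draws
        y[0] = 1 - y[0]
    df = pd.DataFrame(X, columns=cols)
    df["y"] = y
    return df, sets


def brute_r2(df: pd.DataFrame, outcome: str, sets, subset_names) -> float:
    """McFadden R2 of one subset via a fresh, unmemoized fit."""
    cols = [c for s in sets if s.name in set(subset_names) for c in s.columns]
    if not cols:
        return 0.0
    return mcfadden_r2(fit_logistic(df[cols], df[outcome]))


class R2Oracle:
    """Subset-R2 evaluator backed by direct refits (cached per subset)."""

    def __init__(self, df, outcome, sets):
        self.df, self.outcome, self.sets = df, outcome, sets
        self._cache = {}

    def __call__(self, subset_names) -> float:
        key = frozenset(subset_names)
        if key not in self._cache:
            self._cache[key] = brute_r2(self.df, self.outcome, self.sets, key)
        return self._cache[key]


def shapley_by_permutation(df, outcome, sets) -> pd.Series:
    """Shapley weights by averaging marginal contributions over all p! orderings."""
    r2 = R2Oracle(df, outcome, sets)
    names = [s.name for s in sets]
    total = {n: 0.0 for n in names}
    count = 0
    for order in permutations(names):
        so_far = []
        for n in order:
            total[n] += r2(so_far + [n]) - r2(so_far)
            so_far.append(n)
        count += 1
    return pd.Series({n: total[n] / count for n in names})


def conditional_by_enumeration(df, outcome, sets) -> pd.DataFrame:
    """Conditional dominance matrix via an explicit subset loop."""
    r2 = R2Oracle(df, outcome, sets)
    names = [s.name for s in sets]
    p = len(names)
    C = pd.DataFrame(0.0, index=names, columns=[f"level_{k}" for k in range(p)])
    for j in names:
        others = [n for n in names if n != j]
        for k in range(p):
            vals = [r2(list(S) + [j]) - r2(list(S))
                    for S in combinations(others, k)]
            C.loc[j, f"level_{k}"] = float(np.mean(vals))
    return C


def complete_by_enumeration(df, outcome, sets, tol=1e-10) -> pd.DataFrame:
    """Complete-dominance relation via explicit shared-subset comparisons."""
    r2 = R2Oracle(df, outcome, sets)
    names = [s.name for s in sets]
    D = pd.DataFrame("undetermined", index=names, columns=names)
    for i in names:
        for j in names:
            if i == j:
                continue
            others = [n for n in names if n not in (i, j)]
            di, dj = [], []
            for k in range(len(others) + 1):
                for S in combinations(others, k):
                    di.append(r2(list(S) + [i]) - r2(list(S)))
                    dj.append(r2(list(S) + [j]) - r2(list(S)))
            di, dj = np.array(di), np.array(dj)
            if np.all(di > dj + tol):
                D.loc[i, j] = "dominates"
            elif np.all(dj > di + tol):
                D.loc[i, j] = "dominated"
    return D
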