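"""Case-bootstrap stability of dominance statistics and rankings.

Whole respondent rows (outcome and predictors jointly) are resampled with
replacement; the full dominance analysis is recomputed on each resample.
The published robustness check used only ten replications; the default here
is 200, with B=10 reproducing that scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dominance import PredictorSet, dominance_analysis, rank_predictors

logger = logging.getLogger(__name__)

DEFAULT_B = 200


@dataclass
class BootstrapResult:
    """Replicate-level dominance weights and rank-stability summaries."""

    B: int
    seed: int
    weights: pd.DataFrame         # one row per kept replicate, one col per set
    ranks: pd.DataFrame           # dense ranks per replicate (full, no blanking)
    pair_agreement: pd.DataFrame  # [i, j] = share of replicates with G_i > G_j
    dropped: int                  # replicates whose lattice failed

    def rank_distribution(self) -> pd.DataFrame:
        """Share of replicates in which each set attains each rank."""
        out = {}
        for name in self.ranks.columns:
            out[name] = self.ranks[name].value_counts(normalize=True).sort_index()
        return pd.DataFrame(out).T.fillna(0.0)


def _replicate_rng(seed: int, rep: int) -> np.random.Generator:
    # replicate substreams are individually reproducible
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(rep,)))


def bootstrap_dominance(derived: pd.DataFrame, outcome: str,
                        sets: list[PredictorSet] | None = None,
                        B: int = DEFAULT_B, seed: int = 0,
                        resample: bool = True) -> BootstrapResult:
    """Bootstrap the general-dominance weights of one outcome.

    With ``resample=False`` every replicate is the identity sample, so the
    replicate weights must equal the point estimates (a self-check hook).
    Failed replicates are dropped and counted, never imputed.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    n = len(derived)
    weights_rows, ranks_rows = [], []
    dropped = 0
    for rep in range(B):
        if resample:
            idx = _replicate_rng(seed, rep).integers(0, n, size=n)
            sample = derived.iloc[idx].reset_index(drop=True)
        else:
            sample = derived
        try:
            res = dominance_analysis(sample, outcome, sets)
        except Exception as err:  # lattice failure on a degenerate resample
            dropped += 1
            logger.warning("replicate %d dropped: %s", rep, err)
            continue
        weights_rows.append(res.general.rename(rep))
        ranks_rows.append(rank_predictors(res.general, top_k=len(res.sets)).rename(rep))
    if not weights_rows:
        raise RuntimeError("all bootstrap replicates failed")
    W = pd.DataFrame(weights_rows)
    R = pd.DataFrame(ranks_rows)
    cols = W.columns
    A = pd.DataFrame(0.0, index=cols, columns=cols)
    for i in cols:
        for j in cols:
            if i != j:
                A.loc[i, j] = float((W[i] > W[j]).mean())
    return BootstrapResult(B=B, seed=seed, weights=W, ranks=R,
                           pair_agreement=A, dropped=dropped)
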