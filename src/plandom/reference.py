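"""Published reference values from the Swiss health-plan choice analysis.

The general-dominance weight columns below are the printed results of the
original SHP-based study (three outcomes, 16 predictor sets, weights at
3-decimal precision) together with the ranks as printed, where only the six
largest distinct weights receive a rank and ties share one. They serve as
*input data* for the rank-reconstruction check: applying
:func:`plandom.dominance.rank_predictors` to a printed weight column must
reproduce the printed rank column exactly. The underlying microdata are
contract-restricted, so the weights themselves are not recomputable here.
"""

from __future__ import annotations

import pandas as pd

SET_ORDER = (
    "female", "age_groups", "education", "log_income", "married", "urban",
    "good_health", "chronic", "doctor_visits", "hospital_stays",
    "risk_attitude", "openness", "conscientiousness", "extraversion",
    "agreeableness", "neuroticism",
)

_WEIGHTS = {
    "voluntary_deductible": [0.003, 0.023, 0.004, 0.041, 0.000, 0.001, 0.006,
                             0.018, 0.014, 0.004, 0.081, 0.081, 0.081, 0.080,
                             0.081, 0.081],
    "alternative_plan":     [0.000, 0.004, 0.001, 0.042, 0.002, 0.001, 0.001,
                             0.002, 0.001, 0.000, 0.084, 0.084, 0.084, 0.083,
                             0.084, 0.085],
    "supplementary_insurance": [0.001, 0.015, 0.003, 0.070, 0.001, 0.002, 0.000,
                                0.002, 0.003, 0.001, 0.083, 0.082, 0.082, 0.081,
                                0.082, 0.082],
}

_RANKS = {
    "voluntary_deductible": [None, 4, None, 3, None, None, None, 5, 6, None,
                             1, 1, 1, 2, 1, 1],
    "alternative_plan":     [None, 5, None, 4, 6, None, None, 6, None, None,
                             2, 2, 2, 3, 2, 1],
    "supplementary_insurance": [None, 5, 6, 4, None, None, None, None, 6, None,
                                1, 2, 2, 3, 2, 2],
}


def general_dominance_weights(outcome: str) -> pd.Series:
    """Printed general-dominance weights for one outcome, indexed by set."""
    return pd.Series(_WEIGHTS[outcome], index=list(SET_ORDER), name=outcome)


def printed_ranks(outcome: str) -> pd.Series:
    """Printed ranks (blank cells as <NA>) for one outcome."""
    return pd.Series(_RANKS[outcome], index=list(SET_ORDER),
                     dtype="Int64", name=outcome)


OUTCOMES = tuple(_WEIGHTS)
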