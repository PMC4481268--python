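"""Psychometric evaluation of scoring algorithms: reliability, validity,
and conversion to per-dataset rank scores.

Indicators live in a long table (algorithm, indicator, property, value);
properties are ``reliability_splithalf``, ``reliability_retest``,
``validity_direct``, ``validity_indirect`` and ``validity_predictive``.
Rank scores give the highest rank to the best-performing algorithm; the
composite "overall validity" averages the three validity-property rank
scores available in a dataset.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .scoring import AlgorithmSpec, ScoreMatrix, score_table
from .trialdata import CriterionPanel, TrialTable

RELIABILITY_PROPERTIES = ("reliability_splithalf", "reliability_retest")
VALIDITY_PROPERTIES = ("validity_direct", "validity_indirect", "validity_predictive")

_ROLE_TO_PROPERTY = {
    "direct": "validity_direct",
    "indirect": "validity_indirect",
    "behavioral": "validity_predictive",
}

MIN_PAIRS = 3


def _pearson(x: pd.Series, y: pd.Series) -> float:
    """Pairwise-deleted Pearson r; NaN when < MIN_PAIRS complete pairs or
    either variable is constant."""
    ok = x.notna() & y.notna()
    if ok.sum() < MIN_PAIRS:
        return np.nan
    xv, yv = x[ok].to_numpy(float), y[ok].to_numpy(float)
    if np.std(xv) == 0 or np.std(yv) == 0:
        return np.nan
    return float(stats.pearsonr(xv, yv)[0])


def split_halves(table: TrialTable) -> tuple[TrialTable, TrialTable]:
    """Split every block's trials odd/even by within-block presentation
    order (the row order of the table)."""
    df = table.trials
    ordinal = df.groupby(
        ["subject", "session", "pairing", "phase"], observed=False
    ).cumcount()
    odd = TrialTable(
        df[ordinal % 2 == 0].copy(), table.built_in_penalty, table.dataset_label
    )
    even = TrialTable(
        df[ordinal % 2 == 1].copy(), table.built_in_penalty, table.dataset_label
    )
    return odd, even


def _spearman_brown(r: float) -> float:
    if np.isnan(r):
        return np.nan
    if r <= -1:  # Spearman-Brown blows up at r = -1; floor the estimate
        return -1.0
    return float(np.clip(2 * r / (1 + r), -1.0, 1.0))


def split_half_reliability(
    table: TrialTable, spec: AlgorithmSpec, session: int | None = None
) -> float:
    """Odd/even split-half reliability with Spearman-Brown correction.

    Each half is scored with the complete pipeline; the across-subject
    Pearson r is stepped up with 2r / (1 + r) and clamped to [-1, 1].
    Returns NaN with fewer than three complete subject pairs.
    """
    return split_half_reliabilities(table, [spec], session=session).iloc[0]


def split_half_reliabilities(
    table: TrialTable,
    specs: Sequence[AlgorithmSpec],
    session: int | None = None,
) -> pd.Series:
    """Spearman-Brown split-half reliability for many algorithms at once
    (both halves are scored in a single pipeline pass each)."""
    odd, even = split_halves(table)
    s_odd = score_table(odd, specs, session=session).scores
    s_even = score_table(even, specs, session=session).scores.reindex(s_odd.index)
    return pd.Series(
        [_spearman_brown(_pearson(s_odd[c], s_even[c])) for c in s_odd.columns],
        index=s_odd.columns,
        name="splithalf",
    )


def test_retest(scores_session1: pd.Series, scores_session2: pd.Series) -> float:
    """Pearson correlation of the same algorithm's scores across two
    sessions, pairwise-deleted; NaN with fewer than three complete pairs."""
    return _pearson(scores_session1, scores_session2.reindex(scores_session1.index))


def validity_correlations(
    scores: ScoreMatrix | pd.DataFrame, panel: CriterionPanel
) -> pd.DataFrame:
    """Pearson correlation of every algorithm's scores with every criterion
    measure, tagged with the measure's property. Long-format output."""
    df = scores.scores if isinstance(scores, ScoreMatrix) else scores
    rows = []
    for measure in panel.measures.columns:
        role = panel.roles.get(measure)
        if role is None:
            continue
        crit = panel.measures[measure]
        if crit.notna().sum() < MIN_PAIRS:
            continue
        aligned = crit.reindex(df.index)
        for alg in df.columns:
            rows.append(
                {
                    "algorithm": alg,
                    "indicator": measure,
                    "property": _ROLE_TO_PROPERTY[role],
                    "value": _pearson(df[alg], aligned),
                }
            )
    return pd.DataFrame(rows, columns=["algorithm", "indicator", "property", "value"])


def compute_indicators(
    table: TrialTable,
    panel: CriterionPanel | None,
    specs: Sequence[AlgorithmSpec],
    scores: ScoreMatrix | None = None,
) -> pd.DataFrame:
    """Full indicator table for one dataset: split-half reliability for every
    algorithm, test-retest when a second session exists, and validity
    correlations when a criterion panel is supplied."""
    specs = list(specs)
    if scores is None:
        scores = score_table(table, specs)
    halves = split_half_reliabilities(table, specs)
    rows = [
        {
            "algorithm": spec.algorithm_id,
            "indicator": "splithalf",
            "property": "reliability_splithalf",
            "value": halves[spec.algorithm_id],
        }
        for spec in specs
    ]
    sessions = table.sessions
    if len(sessions) >= 2:
        s2 = score_table(table, specs, session=sessions[1])
        for spec in specs:
            rows.append(
                {
                    "algorithm": spec.algorithm_id,
                    "indicator": "retest",
                    "property": "reliability_retest",
                    "value": test_retest(
                        scores.column(spec), s2.column(spec)
                    ),
                }
            )
    out = pd.DataFrame(rows, columns=["algorithm", "indicator", "property", "value"])
    if panel is not None:
        out = pd.concat([out, validity_correlations(scores, panel)], ignore_index=True)
    return out


def rank_indicator(values: pd.Series) -> pd.Series:
    """Midrank the algorithms on one indicator, highest value -> highest
    rank. Missing values stay missing (they never consume a rank)."""
    ok = values.notna()
    ranks = pd.Series(np.nan, index=values.index)
    ranks[ok] = stats.rankdata(values[ok], method="average")
    return ranks


def rank_and_compose(indicators: pd.DataFrame) -> pd.DataFrame:
    """Convert an indicator table to per-property average rank scores plus
    the reliability and overall-validity composites.

    Within each indicator, algorithms are midranked (higher value = higher
    rank = better). Ranks are averaged within property; overall validity is
    the unweighted mean of the validity-property rank scores present;
    reliability is the mean of the reliability-property rank scores present.
    """
    if indicators.empty:
        raise ValueError("empty indicator table")
    n_algorithms = indicators["algorithm"].nunique()
    if n_algorithms < 2:
        raise ValueError("need at least 2 algorithms to rank")

    ranked = []
    for (indicator, prop), sub in indicators.groupby(
        ["indicator", "property"], observed=False
    ):
        values = sub.set_index("algorithm")["value"]
        if values.notna().sum() == 0:
            import warnings

            warnings.warn(f"indicator {indicator!r} is all-missing; excluded")
            continue
        ranks = rank_indicator(values)
        ranked.append(
            pd.DataFrame(
                {"algorithm": ranks.index, "property": prop, "rank": ranks.values}
            )
        )
    long = pd.concat(ranked, ignore_index=True)
    per_property = (
        long.groupby(["algorithm", "property"], observed=False)["rank"]
        .mean()
        .unstack("property")
    )
    out = per_property.copy()
    validity_cols = [c for c in VALIDITY_PROPERTIES if c in per_property.columns]
    if validity_cols:
        out["overall_validity"] = per_property[validity_cols].mean(axis=1)
    reliability_cols = [c for c in RELIABILITY_PROPERTIES if c in per_property.columns]
    if reliability_cols:
        out["reliability"] = per_property[reliability_cols].mean(axis=1)
    return out
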