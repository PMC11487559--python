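"""Validation utilities: ROC/AUC of a state score against binary labels,
dominant-state proportions per group, and two-group rank-sum comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control, mannwhitneyu, rankdata

from .core_io import TCSSResult, ValidationError

__all__ = [
    "roc_auc",
    "DominanceResult",
    "dominant_state_proportions",
    "compare_groups",
]

# Exact null enumeration is cheap up to this combined sample size; beyond it
# the normal approximation with continuity correction is used.
_EXACT_N_MAX = 20


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve via the rank (Mann–Whitney) formula.

    AUC = P(score_pos > score_neg) + 0.5 * P(tie), computed from the rank
    sum of the positive class — the same normalization the unit-mode TCSS
    uses for markers versus background.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValidationError("scores and labels differ in length")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("both classes must be present to compute an AUC")
    ranks = rankdata(scores, method="average")
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class DominanceResult:
    """Per-group distribution of dominant (argmax-score) states."""

    proportions: pd.DataFrame  # groups × states, rows sum to 1
    dominant: pd.Series  # sample -> winning state
    ties: list[str] = field(default_factory=list)  # samples with tied maxima


def dominant_state_proportions(
    result: TCSSResult, groups: pd.Series | dict
) -> DominanceResult:
    """Fraction of samples per group whose top-scoring state is each state.

    Argmax ties are broken by the score table's state order (canonical order
    for standard runs) and the affected samples are recorded in ``ties``.
    """
    groups = pd.Series(groups).astype(str)
    missing = [s for s in result.samples if s not in groups.index]
    if missing:
        raise ValidationError(f"sample {missing[0]!r} has no group assignment")
    scores = result.scores
    states = list(scores.index)
    winners: dict[str, str] = {}
    ties: list[str] = []
    for sample in scores.columns:
        col = scores[sample].to_numpy()
        top = col.max()
        at_top = np.flatnonzero(col == top)
        winners[str(sample)] = states[at_top[0]]
        if len(at_top) > 1:
            ties.append(str(sample))
    dominant = pd.Series(winners, name="dominant_state")
    table = pd.crosstab(groups.loc[dominant.index], dominant, normalize="index")
    table = table.reindex(columns=states, fill_value=0.0)
    table.index.name = "group"
    return DominanceResult(proportions=table, dominant=dominant, ties=ties)


def compare_groups(
    result: TCSSResult,
    groups: pd.Series | dict,
    correction: str | None = None,
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum test per state between two groups.

    The exact null distribution is used when the combined sample size is at
    most 20; larger comparisons use the normal approximation with continuity
    correction.  With ``correction="bh"`` a Benjamini–Hochberg adjusted
    q-value column is added across states.

    Returns a DataFrame indexed by state with columns ``statistic`` (the U
    statistic of group A), ``pvalue``, and group sizes.
    """
    groups = pd.Series(groups).astype(str)
    missing = [s for s in result.samples if s not in groups.index]
    if missing:
        raise ValidationError(f"sample {missing[0]!r} has no group assignment")
    groups = groups.loc[result.samples]
    names = sorted(groups.unique())
    if len(names) != 2:
        raise ValidationError(f"exactly two groups required, got {len(names)}")
    a_samples = groups.index[groups == names[0]]
    b_samples = groups.index[groups == names[1]]
    if len(a_samples) < 2 or len(b_samples) < 2:
        raise ValidationError("each group needs >= 2 samples")

    rows = []
    for state in result.scores.index:
        a = result.scores.loc[state, a_samples].to_numpy()
        b = result.scores.loc[state, b_samples].to_numpy()
        method = "exact" if (len(a) + len(b)) <= _EXACT_N_MAX else "asymptotic"
        res = mannwhitneyu(a, b, alternative="two-sided", method=method)
        rows.append(
            {
                "state": state,
                "statistic": float(res.statistic),
                "pvalue": float(res.pvalue),
                "n_" + names[0]: len(a),
                "n_" + names[1]: len(b),
            }
        )
    table = pd.DataFrame(rows).set_index("state")
    if correction == "bh":
        table["qvalue"] = false_discovery_control(table["pvalue"].to_numpy())
    elif correction is not None:
        raise ValidationError(f"unknown correction {correction!r}")
    return table
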