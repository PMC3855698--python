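"""Confidence escalation over time bins and its relation to model benefit.

Mean absolute confidence is computed per member over the same contiguous
time bins used for model fitting (raw 1..5 magnitudes, before any state
reduction). The escalation index of a member is the change from the
first to the last bin -- relative change (M_last - M_first) / M_first by
default, absolute change selectable -- and the dyad-level escalation is
the sum of its members' indices. Cohort-level escalation is correlated
with model collective benefit by a Pearson product-moment correlation
(two-sided p from the t distribution with n - 2 df).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fitting import split_bins

__all__ = [
    "EscalationSummary",
    "confidence_by_bin",
    "escalation_index",
    "dyad_escalation",
    "correlate_escalation_cb",
]

INDEX_KINDS = ("relative", "absolute")


@dataclass(frozen=True)
class EscalationSummary:
    """Per-member bin means of absolute confidence and the derived index."""

    member: int
    M: tuple[float, ...]
    index: float
    index_kind: str = "relative"


def escalation_index(M: Sequence[float], kind: str = "relative") -> float:
    """Change in mean absolute confidence from the first to the last bin.

    ``relative`` (default): (M_last - M_first) / M_first;
    ``absolute``: M_last - M_first. Intermediate bins do not enter.
    """
    if kind not in INDEX_KINDS:
        raise ValueError(f"kind must be one of {INDEX_KINDS}")
    M = tuple(float(m) for m in M)
    if len(M) < 2:
        raise ValueError("need at least two bin means")
    if not (M[0] > 0):
        raise ValueError("first bin mean must be positive")
    change = M[-1] - M[0]
    return change / M[0] if kind == "relative" else change


def confidence_by_bin(
    trials: pd.DataFrame,
    member: int,
    n_bins: int = 3,
    index_kind: str = "relative",
) -> EscalationSummary:
    """Mean absolute confidence of one member per contiguous time bin."""
    if member not in (1, 2):
        raise ValueError("member must be 1 or 2")
    conf = np.abs(trials[f"c{member}"].to_numpy())
    bins = split_bins(len(trials), n_bins)
    M = tuple(float(conf[idx].mean()) for idx in bins)
    return EscalationSummary(member, M, escalation_index(M, index_kind), index_kind)


def dyad_escalation(summary1: EscalationSummary, summary2: EscalationSummary) -> float:
    """Dyadic cumulative escalation: sum of the two members' indices."""
    if summary1.index_kind != summary2.index_kind:
        raise ValueError("summaries use different index kinds")
    return summary1.index + summary2.index


def correlate_escalation_cb(
    dyad_escalations: Sequence[float],
    cb_models: Sequence[float],
) -> tuple[float, float, int]:
    """Pearson correlation between dyadic escalation and model benefit.

    Returns ``(r, two-sided p, n)``.
    """
    x = np.asarray(dyad_escalations, dtype=float)
    y = np.asarray(cb_models, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-D and equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 dyads")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for constant input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue), n
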