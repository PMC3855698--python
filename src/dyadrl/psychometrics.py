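"""Cumulative-Gaussian psychometric fitting and collective benefit.

The choice curve is ``P(choose 2nd | delta_c) = Phi((delta_c - b) / sigma)``
with bias ``b`` and noise SD ``sigma``, estimated by maximum-likelihood
probit regression (binomial GLM with a probit link, IRLS). Sensitivity is
summarised by the maximum slope of the fitted curve at its inflection,
``s = 1 / (sigma * sqrt(2 * pi))``, and the collective benefit of a
decision maker is the ratio of its slope to the steeper member's slope.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "PsychometricFit",
    "fit_psychometric",
    "fit_from_trials",
    "slope_from_sigma",
    "collective_benefit",
]

_SQRT_2PI = math.sqrt(2.0 * math.pi)


@dataclass(frozen=True)
class PsychometricFit:
    """Result of one probit fit.

    ``converged`` is False for degenerate inputs (a single response
    category, or responses perfectly separated along the stimulus axis);
    in that case ``bias`` and ``sigma`` are NaN and ``slope`` is set to
    the configured ceiling (infinite when no ceiling was given).
    """

    bias: float
    sigma: float
    slope: float
    n_trials: int
    converged: bool


def slope_from_sigma(sigma: float) -> float:
    """Maximum slope of ``Phi((x - b)/sigma)`` at its inflection point.

    Closed form: ``1 / (sigma * sqrt(2 * pi))``.
    """
    if not (sigma > 0):
        raise ValueError("sigma must be positive")
    return 1.0 / (sigma * _SQRT_2PI)


def _degenerate(n: int, slope_ceiling: float | None) -> PsychometricFit:
    cap = math.inf if slope_ceiling is None else float(slope_ceiling)
    return PsychometricFit(math.nan, math.nan, cap, n, False)


def _is_separated(ux: np.ndarray, k: np.ndarray, m: np.ndarray) -> bool:
    """Perfect separation check on binned binomial data (ux sorted)."""
    if np.any((k > 0) & (k < m)):
        return False
    frac = k / m  # each entry exactly 0 or 1 here
    return bool(np.all(np.diff(frac) >= 0) or np.all(np.diff(frac) <= 0))


def fit_psychometric(
    delta_c: Sequence[float],
    chose_second: Sequence[bool],
    slope_ceiling: float | None = None,
    tol: float = 1e-8,
    maxiter: int = 100,
) -> PsychometricFit:
    """Maximum-likelihood probit fit of the psychometric function.

    Parameters
    ----------
    delta_c
        Signed contrast differences, one per trial.
    chose_second
        Whether the second interval was chosen, one per trial.
    slope_ceiling
        Slope assigned to degenerate fits (perfect separation or a single
        response category); ``None`` means unbounded (``inf``).

    Returns
    -------
    PsychometricFit
        With ``bias = -beta0/beta1`` and ``sigma = 1/beta1`` from the
        probit linear predictor ``beta0 + beta1 * delta_c``.

    Raises
    ------
    ValueError
        If fewer than two distinct stimulus levels are present or the
        inputs are malformed.
    """
    x = np.asarray(delta_c, dtype=float)
    y = np.asarray(chose_second, dtype=bool)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("delta_c and chose_second must be 1-D and equal length")
    if not np.all(np.isfinite(x)):
        raise ValueError("delta_c must be finite")
    n = x.size
    ux = np.unique(x)
    if ux.size < 2:
        raise ValueError("need at least 2 distinct delta_c values")

    # Aggregate to binomial counts per stimulus level: identical MLE,
    # much cheaper IRLS than the trial-level design matrix.
    k = np.array([np.count_nonzero(y[x == u]) for u in ux], dtype=float)
    m = np.array([np.count_nonzero(x == u) for u in ux], dtype=float)

    total = k.sum()
    if total == 0 or total == n:
        return _degenerate(n, slope_ceiling)
    if _is_separated(ux, k, m):
        return _degenerate(n, slope_ceiling)

    design = sm.add_constant(ux)
    family = sm.families.Binomial(link=sm.families.links.Probit())
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(np.column_stack([k, m - k]), design, family=family).fit(
                maxiter=maxiter, tol=tol
            )
        beta0, beta1 = (float(v) for v in res.params)
        ok = bool(res.converged) and math.isfinite(beta0) and math.isfinite(beta1)
    except Exception:
        ok = False
    if not ok or beta1 <= 0:
        # Anti-predictive or numerically failed fit: no meaningful slope.
        return PsychometricFit(math.nan, math.nan, math.nan, n, False)
    sigma = 1.0 / beta1
    bias = -beta0 / beta1
    slope = slope_from_sigma(sigma)
    if slope_ceiling is not None and slope > slope_ceiling:
        slope = float(slope_ceiling)
    return PsychometricFit(bias, sigma, slope, n, True)


def fit_from_trials(
    trials: pd.DataFrame,
    role: str,
    slope_ceiling: float | None = None,
) -> PsychometricFit:
    """Fit the psychometric function of one decision maker in a trial table.

    ``role`` is ``"member1"``, ``"member2"`` (individual choices, from the
    sign of the confidence) or ``"dyad"`` (the empirical joint decision).
    """
    if role == "member1":
        chose = trials["c1"].to_numpy() > 0
    elif role == "member2":
        chose = trials["c2"].to_numpy() > 0
    elif role == "dyad":
        chose = trials["dyad_decision"].to_numpy() == 2
    else:
        raise ValueError(f"unknown role {role!r}")
    return fit_psychometric(trials["delta_c"].to_numpy(), chose, slope_ceiling)


def collective_benefit(s_test: float, s_member1: float, s_member2: float) -> float:
    """Ratio of a decision maker's slope to the steeper member's slope.

    Values above 1 mean the tested decision maker beats the dyad's more
    sensitive member. Callers typically log-transform before statistics.
    """
    for s in (s_test, s_member1, s_member2):
        if not (s > 0):
            raise ValueError("all slopes must be positive")
    return s_test / max(s_member1, s_member2)
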