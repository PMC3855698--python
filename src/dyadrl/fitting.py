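"""Learning-rate search under the two model-fitting objectives.

Sessions are split into contiguous equal bins (default 3) and learning is
restarted from a zeroed value table at the start of every bin. Within a
bin the learning rate is chosen from a grid either to maximise the
psychometric slope of the model's own decisions ("max accuracy") or to
maximise trial-by-trial agreement with the joint decisions a given
member indicated ("max similarity"). The winning decision sequences of
the bins are then collapsed and one overall slope is fitted, from which
the model's collective benefit (s_model / s_max) and its concordance
with the empirical dyad (s_model / s_dyad) are derived.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import psychometrics, rl_agent
from .psychometrics import PsychometricFit, collective_benefit, fit_from_trials, fit_psychometric

__all__ = [
    "DEFAULT_ALPHA_GRID",
    "DEFAULT_N_BINS",
    "SLOPE_CEILING_FACTOR",
    "ModelResult",
    "DyadEvaluation",
    "split_bins",
    "fit_max_accuracy",
    "fit_max_similarity",
    "evaluate_dyad",
]

#: Dense default grid over the admissible learning-rate range [0, 1].
DEFAULT_ALPHA_GRID = tuple(round(a, 2) for a in np.linspace(0.0, 1.0, 101))

DEFAULT_N_BINS = 3

#: Degenerate (perfectly separated) fits get their slope capped at this
#: multiple of the steeper member's slope, keeping benefit ratios finite.
SLOPE_CEILING_FACTOR = 10.0


def split_bins(trials, n_bins: int = DEFAULT_N_BINS) -> list[np.ndarray]:
    """Contiguous, order-preserving partition into near-equal bins.

    Accepts a trial table or an integer length. Bin sizes differ by at
    most one; remainder trials go to the earliest bins (256 trials over
    3 bins gives sizes 86, 85, 85).
    """
    n = trials if isinstance(trials, (int, np.integer)) else len(trials)
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if n_bins > n:
        raise ValueError(f"n_bins ({n_bins}) exceeds trial count ({n})")
    base, rem = divmod(n, n_bins)
    sizes = [base + 1] * rem + [base] * (n_bins - rem)
    edges = np.cumsum([0] + sizes)
    return [np.arange(edges[i], edges[i + 1]) for i in range(n_bins)]


def _cell_rng(seed: int, dyad_id: int, bin_idx: int, *extra: int) -> np.random.Generator:
    """Deterministic rng for one (dyad, bin, alpha[, member]) grid cell."""
    seq = np.random.SeedSequence(int(seed), spawn_key=(int(dyad_id), int(bin_idx)) + tuple(int(e) for e in extra))
    return np.random.default_rng(seq)


def _score(slope: float) -> float:
    return slope if (slope is not None and not math.isnan(slope)) else -math.inf


@dataclass
class ModelResult:
    """Fitted model for one dyad under one objective."""

    objective: str
    bin_alphas: list  # per-bin winning alpha; dict {member: alpha} for max_similarity
    bin_scores: list  # per-bin winning objective value (same nesting)
    decisions: np.ndarray  # collapsed model decision per trial
    model_fit: PsychometricFit
    cb_model: float
    concordance: float
    similarity: dict[int, float] | None = None
    events: list[str] = field(default_factory=list)


def _empirical_fits(trials: pd.DataFrame):
    f1 = fit_from_trials(trials, "member1")
    f2 = fit_from_trials(trials, "member2")
    s_max = max(f1.slope, f2.slope)
    ceiling = SLOPE_CEILING_FACTOR * s_max
    fd = fit_from_trials(trials, "dyad", slope_ceiling=ceiling)
    return f1, f2, fd, s_max, ceiling


def fit_max_accuracy(
    trials: pd.DataFrame,
    alpha_grid: Sequence[float] | None = None,
    n_bins: int = DEFAULT_N_BINS,
    seed: int = 0,
    dyad_id: int = 0,
    update_on_agreement: bool = True,
    _fits=None,
) -> ModelResult:
    """Learning-rate search maximising the model's own psychometric slope.

    For each bin independently, every grid alpha is run as a free-mode
    episode restarted from a zeroed table, and the alpha whose decisions
    yield the steepest within-bin slope wins (ties go to the smallest
    alpha). The winning decision sequences are collapsed across bins for
    the overall slope, collective benefit and concordance.
    """
    grid = list(DEFAULT_ALPHA_GRID if alpha_grid is None else alpha_grid)
    if not grid or any(not (0.0 <= a <= 1.0) for a in grid):
        raise ValueError("alpha_grid must be a nonempty subset of [0, 1]")
    f1, f2, fd, s_max, ceiling = _fits if _fits is not None else _empirical_fits(trials)
    events: list[str] = []
    bins = split_bins(trials, n_bins)
    delta_c = trials["delta_c"].to_numpy()

    bin_alphas: list[float] = []
    bin_scores: list[float] = []
    pieces: list[np.ndarray] = []
    for b, idx in enumerate(bins):
        bt = trials.iloc[idx]
        x = delta_c[idx]
        best = None  # (score, alpha, decisions)
        for j, alpha in enumerate(grid):
            trace = rl_agent.run_episode(
                bt, alpha, mode="free", rng=_cell_rng(seed, dyad_id, b, j),
                update_on_agreement=update_on_agreement,
            )
            fit = fit_psychometric(x, trace.actions == 2, slope_ceiling=ceiling)
            if not fit.converged:
                events.append(f"bin {b} alpha {alpha}: degenerate bin fit (slope -> {fit.slope:.4g})")
            score = _score(fit.slope)
            if best is None or score > best[0]:
                best = (score, alpha, trace.actions)
        bin_alphas.append(best[1])
        bin_scores.append(best[0])
        pieces.append(best[2])

    decisions = np.concatenate(pieces)
    model_fit = fit_psychometric(delta_c, decisions == 2, slope_ceiling=ceiling)
    if not model_fit.converged:
        events.append(f"collapsed fit degenerate (slope -> {model_fit.slope:.4g})")
    cb_model = collective_benefit(model_fit.slope, f1.slope, f2.slope)
    concordance = model_fit.slope / fd.slope
    return ModelResult(
        objective="max_accuracy",
        bin_alphas=bin_alphas,
        bin_scores=bin_scores,
        decisions=decisions,
        model_fit=model_fit,
        cb_model=cb_model,
        concordance=concordance,
        events=events,
    )


def fit_max_similarity(
    trials: pd.DataFrame,
    alpha_grid: Sequence[float] | None = None,
    n_bins: int = DEFAULT_N_BINS,
    seed: int = 0,
    dyad_id: int = 0,
    update_on_agreement: bool = True,
    _fits=None,
) -> ModelResult:
    """Per-member learning-rate search maximising similarity to the joint
    decisions that member indicated.

    One learner per member is trained in forced mode (updates follow the
    executed empirical decision and its reward) on all bin trials, and
    scored on the disagreement trials where that member was nominated:
    similarity is the fraction of those trials where the greedy
    prediction matches the empirical joint decision. The aggregate model
    decision on a disagreement trial is the nominated member's winning
    learner's greedy prediction; agreement trials take the common choice.
    """
    grid = list(DEFAULT_ALPHA_GRID if alpha_grid is None else alpha_grid)
    if not grid or any(not (0.0 <= a <= 1.0) for a in grid):
        raise ValueError("alpha_grid must be a nonempty subset of [0, 1]")
    f1, f2, fd, s_max, ceiling = _fits if _fits is not None else _empirical_fits(trials)
    events: list[str] = []
    bins = split_bins(trials, n_bins)
    delta_c = trials["delta_c"].to_numpy()
    c1 = trials["c1"].to_numpy()
    c2 = trials["c2"].to_numpy()
    agree = (c1 > 0) == (c2 > 0)
    nominated = trials["nominated"].to_numpy()
    empirical = trials["dyad_decision"].to_numpy()

    # predictions[member][bin] -> greedy predictions for every bin trial
    predictions: dict[int, list[np.ndarray]] = {1: [], 2: []}
    bin_alphas: list[dict[int, float]] = [dict() for _ in bins]
    bin_scores: list[dict[int, float]] = [dict() for _ in bins]
    matched: dict[int, int] = {1: 0, 2: 0}
    scored: dict[int, int] = {1: 0, 2: 0}

    for member in (1, 2):
        prev_alpha: float | None = None
        for b, idx in enumerate(bins):
            bt = trials.iloc[idx]
            score_mask = (~agree[idx]) & (nominated[idx] == member)
            target = empirical[idx][score_mask]
            if score_mask.any():
                best = None  # (similarity, j, alpha, predictions)
                for j, alpha in enumerate(grid):
                    trace = rl_agent.run_episode(
                        bt, alpha, mode="forced", rng=_cell_rng(seed, dyad_id, b, j, member),
                        update_on_agreement=update_on_agreement,
                    )
                    sim = float(np.mean(trace.greedy[score_mask] == target))
                    if best is None or sim > best[0]:
                        best = (sim, j, alpha, trace.greedy)
                sim, j, alpha, preds = best
                matched[member] += int(round(sim * score_mask.sum()))
                scored[member] += int(score_mask.sum())
            else:
                # Member never nominated in this bin: inherit the nearest
                # previous bin's alpha (smallest grid alpha in bin 0).
                alpha = prev_alpha if prev_alpha is not None else grid[0]
                j = grid.index(alpha)
                sim = math.nan
                events.append(f"member {member} bin {b}: never nominated; alpha falls back to {alpha}")
                trace = rl_agent.run_episode(
                    bt, alpha, mode="forced", rng=_cell_rng(seed, dyad_id, b, j, member),
                    update_on_agreement=update_on_agreement,
                )
                preds = trace.greedy
            bin_alphas[b][member] = alpha
            bin_scores[b][member] = sim
            predictions[member].append(preds)
            prev_alpha = alpha

    decisions = np.empty(len(trials), dtype=int)
    for b, idx in enumerate(bins):
        for pos, t in enumerate(idx):
            if agree[t]:
                decisions[t] = 2 if c1[t] > 0 else 1
            else:
                decisions[t] = predictions[int(nominated[t])][b][pos]

    model_fit = fit_psychometric(delta_c, decisions == 2, slope_ceiling=ceiling)
    if not model_fit.converged:
        events.append(f"collapsed fit degenerate (slope -> {model_fit.slope:.4g})")
    cb_model = collective_benefit(model_fit.slope, f1.slope, f2.slope)
    concordance = model_fit.slope / fd.slope
    similarity = {
        m: (matched[m] / scored[m] if scored[m] else math.nan) for m in (1, 2)
    }
    return ModelResult(
        objective="max_similarity",
        bin_alphas=bin_alphas,
        bin_scores=bin_scores,
        decisions=decisions,
        model_fit=model_fit,
        cb_model=cb_model,
        concordance=concordance,
        similarity=similarity,
        events=events,
    )


@dataclass
class DyadEvaluation:
    """Empirical fits plus fitted models for one dyad."""

    dyad_id: int
    label: str
    member1_fit: PsychometricFit
    member2_fit: PsychometricFit
    dyad_fit: PsychometricFit
    s_max: float
    cb_empirical: float
    results: dict[str, ModelResult]

    def to_rows(self) -> list[dict]:
        """Flatten to per-(objective, bin, member) result rows for CSV."""
        rows = []
        base = {
            "dyad_id": self.label,
            "s_member1": self.member1_fit.slope,
            "s_member2": self.member2_fit.slope,
            "s_dyad": self.dyad_fit.slope,
            "cb_dyad": self.cb_empirical,
        }
        for objective, res in self.results.items():
            for b, alphas in enumerate(res.bin_alphas):
                members = alphas if isinstance(alphas, dict) else {0: alphas}
                for member, alpha in members.items():
                    rows.append(
                        {
                            **base,
                            "objective": objective,
                            "bin": b,
                            "member": member,
                            "alpha": alpha,
                            "s_model": res.model_fit.slope,
                            "cb_model": res.cb_model,
                            "concordance": res.concordance,
                        }
                    )
        return rows


RESULT_COLUMNS = (
    "dyad_id", "objective", "bin", "member", "alpha",
    "s_member1", "s_member2", "s_dyad", "s_model",
    "cb_dyad", "cb_model", "concordance",
)


def evaluate_dyad(
    trials: pd.DataFrame,
    alpha_grid: Sequence[float] | None = None,
    n_bins: int = DEFAULT_N_BINS,
    seed: int = 0,
    dyad_id: int = 0,
    label: str | None = None,
    objectives: Sequence[str] = ("max_accuracy", "max_similarity"),
    update_on_agreement: bool = True,
) -> DyadEvaluation:
    """Fit the empirical psychometrics and the requested model objectives.

    Returns the per-member and dyad slopes, the empirical collective
    benefit (s_dyad / s_max), and one :class:`ModelResult` per objective.
    """
    fits = _empirical_fits(trials)
    f1, f2, fd, s_max, _ = fits
    cb_emp = collective_benefit(fd.slope, f1.slope, f2.slope)
    results: dict[str, ModelResult] = {}
    for objective in objectives:
        if objective == "max_accuracy":
            results[objective] = fit_max_accuracy(
                trials, alpha_grid, n_bins, seed, dyad_id, update_on_agreement, _fits=fits
            )
        elif objective == "max_similarity":
            results[objective] = fit_max_similarity(
                trials, alpha_grid, n_bins, seed, dyad_id, update_on_agreement, _fits=fits
            )
        else:
            raise ValueError(f"unknown objective {objective!r}")
    return DyadEvaluation(
        dyad_id=dyad_id,
        label=label if label is not None else f"dyad_{dyad_id:03d}",
        member1_fit=f1,
        member2_fit=f2,
        dyad_fit=fd,
        s_max=s_max,
        cb_empirical=cb_emp,
        results=results,
    )
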