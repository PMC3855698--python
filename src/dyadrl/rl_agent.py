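"""Single-step temporal-difference learner over confidence-pair states.

The state on each trial is the pair of signed confidences reported by the
two dyad members, reduced by collapsing the two highest confidence levels
(magnitudes 4 and 5 both map to 4), giving an 8 x 8 = 64 cell state
space. The two actions are the two response intervals; reward is +1 for
a correct joint decision and -1 otherwise. Action values are updated by

    Q(s, a) <- Q(s, a) + alpha * (r - Q(s, a))

and actions are selected greedily, falling back to the higher-confidence
member's choice when the two action values are tied (which includes the
first visit to every state, since Q starts at zero).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .synthetic_data import CONFIDENCE_STEPS, VALID_CONFIDENCES

__all__ = [
    "State",
    "QTable",
    "UpdateTrace",
    "AgentTrace",
    "transform_state",
    "td_update",
    "greedy_action",
    "run_episode",
    "confidence_policy_decisions",
]

#: Collapse ceiling of the reduced confidence scale.
MAX_TRANSFORMED = 4


class State(NamedTuple):
    """Reduced confidence-pair state; components in {-4..-1, 1..4}."""

    tc1: int
    tc2: int


def transform_state(c1: int, c2: int) -> State:
    """Map a raw signed confidence pair to its reduced state.

    Magnitudes 4 and 5 are relabelled as 4; magnitudes 1..3 and all signs
    are unchanged. Raw confidences must be in {-5..-1, 1..5}.
    """

    def reduce(c: int) -> int:
        c = int(c)
        if c not in VALID_CONFIDENCES:
            raise ValueError(
                f"confidence must be a nonzero integer in -{CONFIDENCE_STEPS}..{CONFIDENCE_STEPS}, got {c}"
            )
        mag = min(abs(c), MAX_TRANSFORMED)
        return mag if c > 0 else -mag

    return State(reduce(c1), reduce(c2))


@dataclass(frozen=True)
class UpdateTrace:
    """One TD update: delta = reward - q_before; q_after = q_before + alpha*delta."""

    q_before: float
    reward: int
    alpha: float
    delta: float
    q_after: float
    state: State | None = None
    action: int | None = None


def td_update(
    q_before: float,
    reward: int,
    alpha: float,
    state: State | None = None,
    action: int | None = None,
) -> UpdateTrace:
    """Single-step TD update of one action value."""
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must be in [0, 1]")
    if reward not in (-1, 1):
        raise ValueError("reward must be -1 or +1")
    delta = reward - q_before
    q_after = q_before + alpha * delta
    return UpdateTrace(q_before, reward, alpha, delta, q_after, state, action)


class QTable:
    """Sparse table of action values over (State, action) pairs.

    Unvisited pairs have value 0 (the initialisation) and visit count 0.
    """

    __slots__ = ("_q", "_visits")

    def __init__(self) -> None:
        self._q: dict[tuple[State, int], float] = {}
        self._visits: dict[tuple[State, int], int] = {}

    def q(self, state: State, action: int) -> float:
        return self._q.get((state, action), 0.0)

    def visits(self, state: State, action: int) -> int:
        return self._visits.get((state, action), 0)

    def apply(self, trace: UpdateTrace) -> None:
        key = (trace.state, trace.action)
        self._q[key] = trace.q_after
        self._visits[key] = self._visits.get(key, 0) + 1

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (s.tc1, s.tc2, a, self._q[(s, a)], self._visits.get((s, a), 0))
            for (s, a) in sorted(self._q)
        ]
        return pd.DataFrame(rows, columns=["tc1", "tc2", "action", "q", "visits"])


def _higher_confidence_action(state: State, rng: np.random.Generator) -> int:
    """Tie-break rule: follow the member with the larger reduced confidence
    magnitude; on an exact magnitude tie with conflicting signs, pick
    uniformly at random (the only point where the rng is consumed)."""
    a1, a2 = abs(state.tc1), abs(state.tc2)
    if a1 > a2:
        leader = state.tc1
    elif a2 > a1:
        leader = state.tc2
    elif (state.tc1 > 0) == (state.tc2 > 0):
        leader = state.tc1
    else:
        return int(rng.integers(1, 3))
    return 2 if leader > 0 else 1


def greedy_action(qtable: QTable, state: State, rng: np.random.Generator) -> int:
    """Greedy policy over the two actions with confidence-based tie-breaking."""
    q1 = qtable.q(state, 1)
    q2 = qtable.q(state, 2)
    if q1 > q2:
        return 1
    if q2 > q1:
        return 2
    return _higher_confidence_action(state, rng)


@dataclass
class AgentTrace:
    """Per-trial record of one episode plus the final action-value table."""

    alpha: float
    mode: str
    states: list[State]
    greedy: np.ndarray  # greedy policy prediction per trial
    actions: np.ndarray  # executed action per trial
    rewards: np.ndarray
    q_before: np.ndarray
    q_after: np.ndarray
    deltas: np.ndarray
    updated: np.ndarray
    qtable: QTable = field(repr=False)

    @property
    def cumulative_reward(self) -> int:
        return int(self.rewards.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tc1": [s.tc1 for s in self.states],
                "tc2": [s.tc2 for s in self.states],
                "greedy": self.greedy,
                "action": self.actions,
                "reward": self.rewards,
                "q_before": self.q_before,
                "delta": self.deltas,
                "q_after": self.q_after,
                "updated": self.updated,
            }
        )


def run_episode(
    trials: pd.DataFrame,
    alpha: float,
    mode: str = "free",
    rng: np.random.Generator | None = None,
    update_on_agreement: bool = True,
) -> AgentTrace:
    """Run the TD learner once over an ordered block of trials.

    Parameters
    ----------
    trials
        Trial table (canonical columns), ordered by ``trial_index``.
    alpha
        Learning rate in [0, 1].
    mode
        ``"free"``: on agreement trials the agent executes the members'
        common choice; on disagreement trials it executes its greedy
        action. ``"forced"``: the agent executes the empirical
        ``dyad_decision`` on every trial; the greedy prediction is still
        recorded for similarity scoring.
    rng
        Source for the rare equal-confidence tie-break; defaults to a
        fixed-seed generator.
    update_on_agreement
        When False, agreement trials leave the table untouched (their
        trace rows carry ``updated = False`` and a NaN delta).

    The table starts at all zeros; only the executed (state, action) pair
    is updated each trial.
    """
    if mode not in ("free", "forced"):
        raise ValueError("mode must be 'free' or 'forced'")
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must be in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(0)
    idx = trials["trial_index"].to_numpy()
    if not np.all(np.diff(idx) > 0):
        raise ValueError("trials must be strictly ordered by trial_index")
    c1 = trials["c1"].to_numpy()
    c2 = trials["c2"].to_numpy()
    correct = trials["correct_interval"].to_numpy()
    dyad_decision = trials["dyad_decision"].to_numpy()

    n = len(trials)
    qt = QTable()
    states: list[State] = []
    greedy = np.empty(n, dtype=int)
    actions = np.empty(n, dtype=int)
    rewards = np.empty(n, dtype=int)
    q_before = np.empty(n, dtype=float)
    q_after = np.empty(n, dtype=float)
    deltas = np.full(n, math.nan)
    updated = np.zeros(n, dtype=bool)

    for i in range(n):
        s = transform_state(c1[i], c2[i])
        states.append(s)
        agree = (c1[i] > 0) == (c2[i] > 0)
        g = greedy_action(qt, s, rng)
        greedy[i] = g
        if mode == "free":
            a = (2 if c1[i] > 0 else 1) if agree else g
        else:
            a = int(dyad_decision[i])
        actions[i] = a
        r = 1 if a == correct[i] else -1
        rewards[i] = r
        q_before[i] = qt.q(s, a)
        if update_on_agreement or not agree:
            trace = td_update(q_before[i], r, alpha, state=s, action=a)
            qt.apply(trace)
            deltas[i] = trace.delta
            updated[i] = True
        q_after[i] = qt.q(s, a)

    return AgentTrace(
        alpha=alpha,
        mode=mode,
        states=states,
        greedy=greedy,
        actions=actions,
        rewards=rewards,
        q_before=q_before,
        q_after=q_after,
        deltas=deltas,
        updated=updated,
        qtable=qt,
    )


def confidence_policy_decisions(
    trials: pd.DataFrame, rng: np.random.Generator
) -> np.ndarray:
    """Decisions of the pure confidence-following heuristic.

    Agreement trials take the common choice; disagreement trials follow
    the member with the larger reduced confidence magnitude, with a
    seeded coin flip on exact magnitude ties. Consumes the rng in exactly
    the same trials as a free-mode episode with alpha = 0, so the two are
    decision-for-decision comparable under a shared seed.
    """
    c1 = trials["c1"].to_numpy()
    c2 = trials["c2"].to_numpy()
    out = np.empty(len(trials), dtype=int)
    for i in range(len(trials)):
        if (c1[i] > 0) == (c2[i] > 0):
            out[i] = 2 if c1[i] > 0 else 1
        else:
            out[i] = _higher_confidence_action(transform_state(c1[i], c2[i]), rng)
    return out
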