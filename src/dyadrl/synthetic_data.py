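"""Seeded generators for dyadic confidence-sharing sessions.

Each simulated observer is an equal-variance Gaussian signal-detection
model for a two-interval forced choice: on a trial with signed contrast
difference ``delta_c`` the internal evidence is drawn from
``Normal(delta_c - bias, sigma**2)``, the second interval is chosen when
the evidence is positive, and the confidence magnitude (1..5) is obtained
by quantizing the absolute evidence against four ascending thresholds.
This generative model has exactly the cumulative-Gaussian choice curve
``P(choose 2nd) = Phi((delta_c - bias) / sigma)`` that the psychometric
fitting stage assumes, which makes probit recovery an exact oracle.

Confidence escalation is modelled as a geometric decay of the confidence
thresholds over trials: thresholds shrink by a factor
``(1 - escalation_rate)`` per trial, so reported confidence magnitudes
drift upward over a session while choice accuracy is untouched (the
choice depends only on the sign of the evidence).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TRIAL_COLUMNS",
    "DEFAULT_CONTRAST_MAGNITUDES",
    "DEFAULT_THRESHOLD_MULTIPLIERS",
    "CONFIDENCE_STEPS",
    "VALID_CONFIDENCES",
    "ObserverParams",
    "SessionConfig",
    "default_thresholds",
    "simulate_observer_response",
    "simulate_session",
    "simulate_cohort",
    "nominated_keeps_choice",
    "preset_member_drawer",
    "get_preset_drawer",
    "PRESETS",
]

#: Canonical column order of a trial table (the on-disk CSV schema).
TRIAL_COLUMNS = (
    "trial_index",
    "delta_c",
    "c1",
    "c2",
    "correct_interval",
    "nominated",
    "dyad_decision",
)

#: Default contrast-difference magnitudes (unit-normalised contrast).
#: The study design used 4 levels spanning very easy to very difficult;
#: the exact values are not public, so these are config-exposed placeholders.
DEFAULT_CONTRAST_MAGNITUDES = (0.015, 0.035, 0.07, 0.15)

#: Number of confidence steps per interval on the rating scale.
CONFIDENCE_STEPS = 5

#: Admissible signed confidence values: -5..-1 and 1..5, zero excluded.
VALID_CONFIDENCES = frozenset(range(-CONFIDENCE_STEPS, 0)) | frozenset(
    range(1, CONFIDENCE_STEPS + 1)
)

#: Default confidence cut-points expressed in units of the observer's own
#: noise SD; scaling by sigma keeps observers "calibrated" (confidence
#: magnitude maps to evidence strength relative to their own reliability).
DEFAULT_THRESHOLD_MULTIPLIERS = (0.5, 1.0, 1.6, 2.3)

#: Signature of a pluggable rule resolving disagreement trials:
#: ``rule(c1, c2, nominated, rng) -> joint decision in {1, 2}``.
ArbitrationRule = Callable[[int, int, int, np.random.Generator], int]


def default_thresholds(sigma: float) -> tuple[float, ...]:
    """Confidence cut-points scaled to an observer's own noise SD."""
    return tuple(sigma * m for m in DEFAULT_THRESHOLD_MULTIPLIERS)


@dataclass(frozen=True)
class ObserverParams:
    """Generative parameters of one signal-detection observer.

    Parameters
    ----------
    bias
        Additive response bias ``b`` in contrast units.
    sigma
        Evidence noise SD in contrast units; must be positive.
    conf_thresholds
        Four strictly increasing positive cut-points mapping absolute
        evidence to a confidence magnitude in 1..5.
    escalation_rate
        Per-trial multiplicative decay of the thresholds; 0 disables
        escalation. Must lie in ``[0, 1)``.
    """

    bias: float
    sigma: float
    conf_thresholds: tuple[float, ...]
    escalation_rate: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "conf_thresholds", tuple(float(t) for t in self.conf_thresholds))
        if not math.isfinite(self.bias):
            raise ValueError("bias must be finite")
        if not (self.sigma > 0 and math.isfinite(self.sigma)):
            raise ValueError("sigma must be positive and finite")
        thr = self.conf_thresholds
        if len(thr) != CONFIDENCE_STEPS - 1:
            raise ValueError(
                f"conf_thresholds must have {CONFIDENCE_STEPS - 1} entries, got {len(thr)}"
            )
        if any(t <= 0 for t in thr) or any(b <= a for a, b in zip(thr, thr[1:])):
            raise ValueError("conf_thresholds must be strictly increasing and positive")
        if not (0.0 <= self.escalation_rate < 1.0):
            raise ValueError("escalation_rate must be in [0, 1)")


@dataclass(frozen=True)
class SessionConfig:
    """Design of one dyadic session.

    Defaults reproduce the 16 blocks x 16 trials = 256 trial layout with
    4 contrast-difference magnitudes.
    """

    members: tuple[ObserverParams, ObserverParams]
    seed: int
    n_blocks: int = 16
    trials_per_block: int = 16
    contrast_magnitudes: tuple[float, ...] = DEFAULT_CONTRAST_MAGNITUDES

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "contrast_magnitudes", tuple(float(m) for m in self.contrast_magnitudes)
        )
        if len(self.members) != 2:
            raise ValueError("members must contain exactly two ObserverParams")
        if self.n_blocks < 1 or self.trials_per_block < 1:
            raise ValueError("n_blocks and trials_per_block must be >= 1")
        mags = self.contrast_magnitudes
        if len(mags) < 1 or any(m <= 0 for m in mags) or len(set(mags)) != len(mags):
            raise ValueError("contrast_magnitudes must be distinct and positive")

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block


def simulate_observer_response(
    delta_c: float,
    params: ObserverParams,
    trial_index: int,
    rng: np.random.Generator,
) -> int:
    """Draw one signed confidence response from a generative observer.

    The returned integer is in ``{-5..-1, 1..5}``; its sign encodes the
    chosen interval (negative = first, positive = second) and its
    magnitude the confidence level. The implied probability of choosing
    the second interval is ``Phi((delta_c - bias) / sigma)``, independent
    of ``trial_index``; escalation only inflates confidence magnitudes.
    """
    if not isinstance(params, ObserverParams):
        raise TypeError("params must be an ObserverParams")
    if trial_index < 0:
        raise ValueError("trial_index must be >= 0")
    x = (delta_c - params.bias) + params.sigma * rng.standard_normal()
    decay = (1.0 - params.escalation_rate) ** trial_index
    ax = abs(x)
    magnitude = 1 + sum(1 for t in params.conf_thresholds if t * decay < ax)
    magnitude = min(magnitude, CONFIDENCE_STEPS)
    return magnitude if x > 0 else -magnitude


def nominated_keeps_choice(
    c1: int, c2: int, nominated: int, rng: np.random.Generator
) -> int:
    """Default arbitration on disagreement: the nominated member keeps
    their own individual choice as the joint decision."""
    c = c1 if nominated == 1 else c2
    return 2 if c > 0 else 1


def simulate_session(
    config: SessionConfig,
    arbitration: ArbitrationRule | None = None,
) -> pd.DataFrame:
    """Simulate one full dyadic session.

    Returns a trial table with the canonical columns (:data:`TRIAL_COLUMNS`),
    one row per trial, fully reproducible from ``config.seed``. The signed
    contrast difference has its magnitude drawn uniformly from
    ``config.contrast_magnitudes`` and its sign (the target interval)
    uniform. A responder is nominated uniformly on every trial; on
    disagreement trials the arbitration rule determines the joint
    decision (default: nominated member keeps their own choice).
    """
    if arbitration is None:
        arbitration = nominated_keeps_choice
    rng = np.random.default_rng(config.seed)
    mags = config.contrast_magnitudes
    m1, m2 = config.members
    rows = []
    for t in range(config.n_trials):
        mag = mags[int(rng.integers(len(mags)))]
        correct_interval = int(rng.integers(1, 3))
        delta_c = mag if correct_interval == 2 else -mag
        c1 = simulate_observer_response(delta_c, m1, t, rng)
        c2 = simulate_observer_response(delta_c, m2, t, rng)
        nominated = int(rng.integers(1, 3))
        if (c1 > 0) == (c2 > 0):
            dyad_decision = 2 if c1 > 0 else 1
        else:
            dyad_decision = int(arbitration(c1, c2, nominated, rng))
        rows.append((t, delta_c, c1, c2, correct_interval, nominated, dyad_decision))
    return pd.DataFrame(rows, columns=list(TRIAL_COLUMNS))


# ---------------------------------------------------------------------------
# Cohorts

#: Named parameter-draw presets. "V" mimics a visual-only communication
#: regime (mild escalation); "VV" mimics visual+verbal (strong escalation);
#: "calibrated" has no escalation at all.
PRESETS: dict[str, dict] = {
    "V": {"escalation_range": (0.0005, 0.002)},
    "VV": {"escalation_range": (0.004, 0.008)},
    "calibrated": {"escalation_range": (0.0, 0.0)},
}

MemberDrawer = Callable[[np.random.Generator], tuple[ObserverParams, ObserverParams]]


def preset_member_drawer(
    sigma_range: tuple[float, float] = (0.05, 0.15),
    bias_range: tuple[float, float] = (-0.01, 0.01),
    escalation_range: tuple[float, float] = (0.0, 0.0),
    threshold_multipliers: Sequence[float] = DEFAULT_THRESHOLD_MULTIPLIERS,
) -> MemberDrawer:
    """Build a per-dyad parameter drawer sampling each member independently.

    Sigmas, biases and escalation rates are uniform on the given ranges;
    confidence thresholds are the multipliers scaled by each member's own
    sigma (calibrated confidence).
    """

    def draw(rng: np.random.Generator) -> tuple[ObserverParams, ObserverParams]:
        members = []
        for _ in range(2):
            sigma = float(rng.uniform(*sigma_range))
            bias = float(rng.uniform(*bias_range))
            esc = float(rng.uniform(*escalation_range))
            thr = tuple(sigma * m for m in threshold_multipliers)
            members.append(ObserverParams(bias, sigma, thr, esc))
        return members[0], members[1]

    return draw


def get_preset_drawer(name: str) -> MemberDrawer:
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return preset_member_drawer(**PRESETS[name])


MANIFEST_COLUMNS = (
    "dyad_id",
    "member",
    "session_seed",
    "bias",
    "sigma",
    "thr1",
    "thr2",
    "thr3",
    "thr4",
    "escalation_rate",
)


def simulate_cohort(
    n_dyads: int,
    draw_members: MemberDrawer | str,
    seed: int,
    n_blocks: int = 16,
    trials_per_block: int = 16,
    contrast_magnitudes: Sequence[float] = DEFAULT_CONTRAST_MAGNITUDES,
    arbitration: ArbitrationRule | None = None,
) -> tuple[list[pd.DataFrame], pd.DataFrame]:
    """Simulate a cohort of independent dyads.

    Every dyad gets an independent child seed spawned from the master
    ``seed``; drawn parameters are recorded in the returned manifest so
    parameter-recovery tests can compare estimates to ground truth.

    Returns
    -------
    sessions : list of DataFrame
        One trial table per dyad, in dyad order.
    manifest : DataFrame
        Two rows per dyad (one per member) with the drawn parameters and
        the derived session seed.
    """
    if n_dyads < 1:
        raise ValueError("n_dyads must be >= 1")
    if isinstance(draw_members, str):
        draw_members = get_preset_drawer(draw_members)
    master = np.random.SeedSequence(seed)
    sessions: list[pd.DataFrame] = []
    manifest_rows = []
    for dyad_id, child in enumerate(master.spawn(n_dyads)):
        param_seq, session_seq = child.spawn(2)
        m1, m2 = draw_members(np.random.default_rng(param_seq))
        session_seed = int(session_seq.generate_state(1)[0])
        config = SessionConfig(
            members=(m1, m2),
            seed=session_seed,
            n_blocks=n_blocks,
            trials_per_block=trials_per_block,
            contrast_magnitudes=tuple(contrast_magnitudes),
        )
        sessions.append(simulate_session(config, arbitration))
        for member_idx, m in enumerate((m1, m2), start=1):
            manifest_rows.append(
                (dyad_id, member_idx, session_seed, m.bias, m.sigma)
                + m.conf_thresholds
                + (m.escalation_rate,)
            )
    manifest = pd.DataFrame(manifest_rows, columns=list(MANIFEST_COLUMNS))
    return sessions, manifest
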