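"""Adapted beads task ("fish-lake" task) structure and ideal-observer oracle.

The task: on each round fish are angled one at a time from one of two hidden
lakes — the "trout lake" (70% trout, 30% carp) or the "carp lake" (30% trout,
70% carp).  Before the first fish a probabilistic auditory cue is played: a
low-pitched tone is associated with the trout lake and a high-pitched tone
with the carp lake, each valid on 80% of rounds.  After every draw the subject
reports a continuous belief g in [0, 1] (1 = certain the trout lake is the
source) and either commits to a final lake choice, ending the round, or draws
again.  Each round opens with one fish already angled, so the first report
follows the first observation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "TaskConfig",
    "RoundSpec",
    "TrialRecord",
    "generate_rounds",
    "draw_fish",
    "ideal_posterior",
    "TONE_FOR_LAKE",
]

#: tone pitch deterministically associated with each lake when the cue is valid
TONE_FOR_LAKE = {"trout": "low", "carp": "high"}
LAKE_FOR_TONE = {"low": "trout", "high": "carp"}


@dataclass(frozen=True)
class TaskConfig:
    """Design constants of the fish-lake task.

    Parameters
    ----------
    urn_major_prob : float
        Proportion of the majority species in each lake (trout in the trout
        lake, carp in the carp lake).  Must lie in (0.5, 1).
    tone_validity : float
        Probability that the round's tone matches the true lake, in [0.5, 1].
    n_rounds : int
        Number of rounds per subject.
    max_draws_per_round : int
        Hard cap on draws within a round; synthetic agents are forced to
        commit at this draw.
    seed : int, optional
        Recorded for provenance; generation functions take an explicit
        numpy Generator.
    """

    urn_major_prob: float = 0.70
    tone_validity: float = 0.80
    n_rounds: int = 30
    max_draws_per_round: int = 20
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.5 < self.urn_major_prob < 1.0:
            raise ValueError("urn_major_prob must lie in (0.5, 1)")
        if not 0.5 <= self.tone_validity <= 1.0:
            raise ValueError("tone_validity must lie in [0.5, 1]")
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be >= 1")
        if self.max_draws_per_round < 1:
            raise ValueError("max_draws_per_round must be >= 1")


@dataclass(frozen=True)
class RoundSpec:
    """One round: the hidden source lake and the (fixed) tone pitch."""

    round_index: int
    true_lake: str  # {"carp", "trout"}
    tone: str  # {"high", "low"}; constant within the round

    def __post_init__(self) -> None:
        if self.true_lake not in ("carp", "trout"):
            raise ValueError(f"unknown lake {self.true_lake!r}")
        if self.tone not in ("high", "low"):
            raise ValueError(f"unknown tone {self.tone!r}")


@dataclass(frozen=True)
class TrialRecord:
    """One draw: the observation and the subject's response to it.

    ``observation`` is 1 for a trout, 0 for a carp; ``reported_belief`` is the
    position of the response bar scaled to [0, 1] (1 = certain trout lake).
    Exactly the last draw of a round carries ``committed=True`` together with
    the final lake choice.
    """

    subject_id: str
    round_index: int
    draw_index: int  # 1-based
    tone: str
    observation: int
    reported_belief: float
    committed: bool
    final_choice: Optional[str] = None

    def __post_init__(self) -> None:
        if self.observation not in (0, 1):
            raise ValueError("observation must be 0 (carp) or 1 (trout)")
        if not 0.0 <= self.reported_belief <= 1.0:
            raise ValueError("reported_belief must lie in [0, 1]")
        if self.draw_index < 1:
            raise ValueError("draw_index is 1-based")


def generate_rounds(config: TaskConfig, rng: np.random.Generator) -> list[RoundSpec]:
    """Draw the round structure: uniform lakes, tones valid w.p. ``tone_validity``."""
    rounds = []
    for i in range(config.n_rounds):
        lake = "trout" if rng.random() < 0.5 else "carp"
        valid = rng.random() < config.tone_validity
        tone = TONE_FOR_LAKE[lake] if valid else TONE_FOR_LAKE["carp" if lake == "trout" else "trout"]
        rounds.append(RoundSpec(round_index=i + 1, true_lake=lake, tone=tone))
    return rounds


def draw_fish(round_spec: RoundSpec, config: TaskConfig, rng: np.random.Generator) -> int:
    """Angle one fish from the round's lake; returns 1 for trout, 0 for carp."""
    p_trout = config.urn_major_prob if round_spec.true_lake == "trout" else 1.0 - config.urn_major_prob
    return int(rng.random() < p_trout)


def ideal_posterior(
    tone: Optional[str],
    n_trout: int,
    n_carp: int,
    config: TaskConfig = TaskConfig(),
) -> float:
    """Exact Bayesian posterior probability of the trout lake.

    The prior comes from the tone (``tone_validity`` for the associated lake,
    0.5 when ``tone`` is None); each trout multiplies the trout-lake odds by
    q/(1-q) with q = ``urn_major_prob`` and each carp by (1-q)/q.  Computed in
    log-odds space for numerical stability at large counts.
    """
    if n_trout < 0 or n_carp < 0:
        raise ValueError("counts must be non-negative")
    if tone is None:
        prior = 0.5
    elif tone == "low":
        prior = config.tone_validity
    elif tone == "high":
        prior = 1.0 - config.tone_validity
    else:
        raise ValueError(f"unknown tone {tone!r}")
    q = config.urn_major_prob
    if prior in (0.0, 1.0):
        return prior
    log_odds = (
        np.log(prior) - np.log1p(-prior)
        + (n_trout - n_carp) * (np.log(q) - np.log1p(-q))
    )
    return float(1.0 / (1.0 + np.exp(-log_odds)))


def rounds_to_frame(rounds: Iterable[RoundSpec]) -> pd.DataFrame:
    """Tabulate RoundSpec records (CSV-ready)."""
    return pd.DataFrame(
        [{"round": r.round_index, "true_lake": r.true_lake, "tone": r.tone} for r in rounds]
    )
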