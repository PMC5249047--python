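"""Belief-update models for the fish-lake task.

Beliefs live on [0, 1] with 1 = certainty in the trout lake.  A round opens
with a tone-shifted prior belief

    b1 = 0.5 + theta   (low-pitched, trout-lake tone)
    b1 = 0.5 - theta   (high-pitched, carp-lake tone)

and each observation o in {0, 1} (1 = trout) moves the belief toward o.  The
linear (Rescorla–Wagner style) rule is

    b <- b + alpha * (o - b)

while the non-linear rule divisively attenuates large prediction errors,

    b <- b + alpha * (o - b) / (zeta * |o - b| + 1),

so that the effective learning rate alpha / (zeta*delta + 1) adaptively
shrinks when the new observation is surprising (delta = |o - b| large).  At
zeta = 0 the two rules coincide; because the step is always a sub-unit
fraction of the distance to o, beliefs can never overshoot [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "ModelParams",
    "MODEL_REGISTRY",
    "initial_belief",
    "update_linear",
    "update_nonlinear",
    "effective_learning_rate",
    "predict_trajectory",
]

THETA_BOUNDS = (0.0, 0.5)
ALPHA_BOUNDS = (0.0, 1.0)
ZETA_BOUNDS = (0.0, 5.0)

#: model_id -> tuple of free parameter names; the rest are fixed at 0
MODEL_REGISTRY = {
    "nonlinear": ("theta", "alpha", "zeta"),
    "linear": ("theta", "alpha"),
    "nonlinear_no_tone": ("alpha", "zeta"),
    "linear_no_tone": ("alpha",),
}

_TONE_SIGN = {"low": 1.0, "high": -1.0, None: 0.0, "none": 0.0}


@dataclass(frozen=True)
class ModelParams:
    """Subject-level parameters of a belief-update model.

    ``theta`` shifts the round-initial belief toward the tone-cued lake,
    ``alpha`` is the constant learning rate, ``zeta`` the degree of
    non-linearity (0 = linear).  ``model_id`` selects which parameters are
    free; fixed parameters must be 0.
    """

    theta: float = 0.0
    alpha: float = 0.5
    zeta: float = 0.0
    model_id: str = "nonlinear"

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_REGISTRY:
            raise ValueError(f"unknown model_id {self.model_id!r}")
        free = MODEL_REGISTRY[self.model_id]
        if not THETA_BOUNDS[0] <= self.theta <= THETA_BOUNDS[1]:
            raise ValueError("theta outside [0, 0.5]")
        if not ALPHA_BOUNDS[0] <= self.alpha <= ALPHA_BOUNDS[1]:
            raise ValueError("alpha outside [0, 1]")
        if not ZETA_BOUNDS[0] <= self.zeta <= ZETA_BOUNDS[1]:
            raise ValueError("zeta outside [0, 5]")
        if "zeta" not in free and self.zeta != 0.0:
            raise ValueError(f"{self.model_id} fixes zeta = 0")
        if "theta" not in free and self.theta != 0.0:
            raise ValueError(f"{self.model_id} fixes theta = 0")

    @property
    def free_names(self) -> tuple[str, ...]:
        return MODEL_REGISTRY[self.model_id]


def initial_belief(theta: float, tone: Optional[str]) -> float:
    """Round-initial belief 0.5 +/- theta depending on the tone pitch."""
    if not THETA_BOUNDS[0] <= theta <= THETA_BOUNDS[1]:
        raise ValueError("theta outside [0, 0.5]")
    if tone not in _TONE_SIGN:
        raise ValueError(f"unknown tone {tone!r}")
    return 0.5 + _TONE_SIGN[tone] * theta


def update_linear(b: float, o: float, alpha: float) -> float:
    """One linear prediction-error update: b + alpha*(o - b)."""
    _check_update_inputs(b, o, alpha)
    return b + alpha * (o - b)


def update_nonlinear(b: float, o: float, alpha: float, zeta: float) -> float:
    """One saturating update: b + alpha*(o - b)/(zeta*|o - b| + 1).

    Equals the linear rule at zeta = 0; larger zeta attenuates the impact of
    large prediction errors while leaving small-error learning (slope alpha
    at delta -> 0) intact.
    """
    _check_update_inputs(b, o, alpha)
    if not ZETA_BOUNDS[0] <= zeta <= ZETA_BOUNDS[1]:
        raise ValueError("zeta outside [0, 5]")
    delta = o - b
    return b + alpha * delta / (zeta * abs(delta) + 1.0)


def effective_learning_rate(alpha: float, zeta: float, delta: float) -> float:
    """Dynamic learning rate alpha/(zeta*delta + 1) at prediction-error magnitude delta."""
    if not 0.0 <= delta <= 1.0:
        raise ValueError("delta outside [0, 1]")
    return alpha / (zeta * delta + 1.0)


def _check_update_inputs(b: float, o: float, alpha: float) -> None:
    if not 0.0 <= b <= 1.0:
        raise ValueError("belief outside [0, 1]")
    if o not in (0, 1, 0.0, 1.0):
        raise ValueError("observation must be binary")
    if not ALPHA_BOUNDS[0] <= alpha <= ALPHA_BOUNDS[1]:
        raise ValueError("alpha outside [0, 1]")


def predict_trajectory(
    params: ModelParams,
    rounds: Iterable[tuple[Optional[str], Sequence[int]]],
) -> list[np.ndarray]:
    """Model-predicted belief trajectory, one array per round.

    ``rounds`` is an iterable of ``(tone, observations)`` pairs.  Within a
    round the belief starts at ``initial_belief`` and is folded through the
    model's update rule; the i-th entry of each array is the belief *after*
    observation i, aligned 1:1 with the round's draws.  A round with no
    observations yields the single-element array ``[initial_belief]``.  The
    belief resets at every new round.

    This is the plain reference implementation; the fitting code uses a
    numerically identical compiled kernel (see :mod:`beadtask._core`).
    """
    out: list[np.ndarray] = []
    for tone, obs in rounds:
        b = initial_belief(params.theta, tone)
        if len(obs) == 0:
            out.append(np.array([b]))
            continue
        traj = np.empty(len(obs))
        for i, o in enumerate(obs):
            if params.model_id.startswith("linear"):
                b = update_linear(b, o, params.alpha)
            else:
                b = update_nonlinear(b, o, params.alpha, params.zeta)
            traj[i] = b
        out.append(traj)
    return out
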