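"""Compiled inner loops for trajectory prediction and the Gaussian likelihood.

Subject data are flattened into contiguous arrays: ``obs`` (0/1 per draw),
``belief`` (reported beliefs per draw), ``round_start`` (CSR-style offsets,
length n_rounds+1) and ``tone_sign`` (+1 low tone, -1 high tone, 0 none, one
per round).  The kernels are exact re-statements of the pure-python update
rules in :mod:`beadtask.models` and are tested against them.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["trajectory_flat", "gaussian_nll", "pack_subject"]

LOG_2PI = float(np.log(2.0 * np.pi))


@njit(cache=True)
def trajectory_flat(obs, round_start, tone_sign, theta, alpha, zeta):
    """Predicted post-update belief for every draw, flat across rounds."""
    n = obs.shape[0]
    out = np.empty(n)
    for r in range(round_start.shape[0] - 1):
        b = 0.5 + tone_sign[r] * theta
        for i in range(round_start[r], round_start[r + 1]):
            d = obs[i] - b
            ad = d if d >= 0.0 else -d
            b = b + alpha * d / (zeta * ad + 1.0)
            out[i] = b
    return out


@njit(cache=True)
def gaussian_nll(obs, belief, round_start, tone_sign, theta, alpha, zeta, sigma):
    """-log N(g | b(params), sigma^2) summed over all draws."""
    n = obs.shape[0]
    nll = 0.5 * n * (LOG_2PI + 2.0 * np.log(sigma))
    inv2s2 = 0.5 / (sigma * sigma)
    for r in range(round_start.shape[0] - 1):
        b = 0.5 + tone_sign[r] * theta
        for i in range(round_start[r], round_start[r + 1]):
            d = obs[i] - b
            ad = d if d >= 0.0 else -d
            b = b + alpha * d / (zeta * ad + 1.0)
            resid = belief[i] - b
            nll += resid * resid * inv2s2
    return nll


def pack_subject(trials):
    """Flatten one subject's trial table into kernel-ready arrays.

    ``trials`` is a DataFrame with columns round, draw, tone, fish, belief
    (any extra columns are ignored).  Rows are sorted by (round, draw); the
    tone must be constant within each round.
    """
    t = trials.sort_values(["round", "draw"])
    obs = t["fish"].to_numpy(dtype=np.float64)
    belief = t["belief"].to_numpy(dtype=np.float64)
    rounds = t["round"].to_numpy()
    boundaries = np.flatnonzero(np.diff(rounds)) + 1
    round_start = np.concatenate(([0], boundaries, [len(rounds)])).astype(np.int64)
    sign_map = {"low": 1.0, "high": -1.0, "none": 0.0}
    tones = t["tone"].to_numpy()
    tone_sign = np.array(
        [sign_map[tones[s]] for s in round_start[:-1]], dtype=np.float64
    )
    return obs, belief, round_start, tone_sign
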