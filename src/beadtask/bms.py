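"""Random-effects Bayesian model selection (RFX-BMS).

Given an n_subjects x K matrix of per-subject log model evidences, the
population is modelled as a mixture: each subject uses one of the K models,
with unknown population frequencies r ~ Dirichlet(alpha).  A variational
update alternates subject-level model responsibilities u_nk with the
Dirichlet concentrations alpha_k.  From the fitted Dirichlet one obtains

* expected model frequencies  r_k = alpha_k / sum(alpha),
* exceedance probabilities    ep_k = P(r_k > r_j for all j),
* the Bayesian omnibus risk   BOR = P(all frequencies equal | data),
* protected exceedance probs  pxp_k = (1 - BOR) ep_k + BOR / K,

the last guarding the exceedance statement against the possibility that
observed evidence differences are chance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import betainc, gammaln, logsumexp, psi

__all__ = [
    "BMSResult",
    "fit_rfx",
    "exceedance_prob",
    "bayes_omnibus_risk",
    "protected_ep",
    "random_effects_bms",
]


@dataclass
class BMSResult:
    """Outcome of random-effects model selection over K models."""

    labels: tuple
    dirichlet_alpha: np.ndarray
    expected_freq: np.ndarray
    ep: np.ndarray
    bor: float
    pxp: np.ndarray
    responsibilities: np.ndarray
    n_iter: int
    n_mc_samples: int
    seed: Optional[int]

    def summary(self) -> str:
        lines = [
            "Random-effects Bayesian model selection",
            "=" * 55,
            f"subjects: {self.responsibilities.shape[0]}   models: {len(self.labels)}"
            f"   BOR: {self.bor:.4f}",
            "-" * 55,
            f"{'model':<20}{'alpha':>8}{'E[freq]':>9}{'EP':>9}{'PXP':>9}",
        ]
        for k, lab in enumerate(self.labels):
            lines.append(
                f"{str(lab):<20}{self.dirichlet_alpha[k]:>8.2f}"
                f"{self.expected_freq[k]:>9.3f}{self.ep[k]:>9.3f}{self.pxp[k]:>9.3f}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "labels": list(map(str, self.labels)),
            "dirichlet_alpha": self.dirichlet_alpha.tolist(),
            "expected_freq": self.expected_freq.tolist(),
            "ep": self.ep.tolist(),
            "bor": self.bor,
            "pxp": self.pxp.tolist(),
            "n_iter": self.n_iter,
            "n_mc_samples": self.n_mc_samples,
            "seed": self.seed,
        }


def _validate(L: np.ndarray) -> np.ndarray:
    L = np.asarray(L, dtype=float)
    if L.ndim != 2 or L.shape[1] < 2:
        raise ValueError("need an n_subjects x K (K >= 2) evidence matrix")
    if not np.all(np.isfinite(L)):
        raise ValueError("log evidences must be finite")
    return L


def fit_rfx(
    L: np.ndarray,
    alpha0: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 10000,
) -> tuple[np.ndarray, np.ndarray]:
    """Variational Dirichlet fit of the random-effects model.

    Iterates  u_nk ∝ exp(L_nk + psi(alpha_k) - psi(sum alpha)),  normalised
    per subject, and  alpha_k = alpha0 + sum_n u_nk,  until the largest
    concentration change falls below ``tol``.  Returns (alpha, u).
    """
    alpha, u, _ = _fit_rfx_iter(L, alpha0, tol, max_iter)
    return alpha, u


def _fit_rfx_iter(L, alpha0, tol, max_iter):
    L = _validate(L)
    n, K = L.shape
    alpha = np.full(K, alpha0, dtype=float)
    u = np.full((n, K), 1.0 / K)
    for it in range(max_iter):
        log_u = L + psi(alpha) - psi(alpha.sum())
        log_u -= logsumexp(log_u, axis=1, keepdims=True)
        u = np.exp(log_u)
        alpha_new = alpha0 + u.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            return alpha_new, u, it + 1
        alpha = alpha_new
    raise RuntimeError(
        f"RFX-BMS did not converge in {max_iter} iterations (last alpha={alpha})"
    )


def exceedance_prob(
    dirichlet_alpha: np.ndarray,
    n_samples: int = 1_000_000,
    seed: Optional[int] = None,
    exact_k2: bool = True,
) -> np.ndarray:
    """P(model k has the largest population frequency) under Dirichlet(alpha).

    For K=2 the exact Beta tail P(Beta(a1, a2) > 1/2) is used unless
    ``exact_k2=False``; otherwise (and for K>2) Monte-Carlo sampling.
    """
    alpha = np.asarray(dirichlet_alpha, dtype=float)
    if np.any(alpha <= 0):
        raise ValueError("Dirichlet concentrations must be positive")
    K = len(alpha)
    if K == 2 and exact_k2:
        p1 = 1.0 - betainc(alpha[0], alpha[1], 0.5)
        return np.array([p1, 1.0 - p1])
    rng = np.random.default_rng(seed)
    samples = rng.dirichlet(alpha, size=int(n_samples))
    winners = np.argmax(samples, axis=1)
    return np.bincount(winners, minlength=K) / len(winners)


def _dirichlet_kl(alpha: np.ndarray, alpha0: float) -> float:
    """KL(Dirichlet(alpha) || Dirichlet(alpha0 * 1)) in closed form."""
    a0 = np.full_like(alpha, alpha0)
    asum, a0sum = alpha.sum(), a0.sum()
    return float(
        gammaln(asum) - gammaln(a0sum)
        - np.sum(gammaln(alpha) - gammaln(a0))
        + np.sum((alpha - a0) * (psi(alpha) - psi(asum)))
    )


def bayes_omnibus_risk(
    L: np.ndarray,
    dirichlet_alpha: np.ndarray,
    responsibilities: np.ndarray,
    alpha0: float = 1.0,
) -> float:
    """Posterior probability that all models are equally frequent.

    Compares the free energy F1 of the fitted random-effects model with the
    evidence F0 of the null in which every subject picks a model uniformly at
    random; BOR = 1 / (1 + exp(F1 - F0)).
    """
    L = _validate(L)
    n, K = L.shape
    alpha = np.asarray(dirichlet_alpha, float)
    u = np.asarray(responsibilities, float)
    F0 = float(np.sum(logsumexp(L - np.log(K), axis=1)))
    digamma_term = psi(alpha) - psi(alpha.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        entropy = -np.where(u > 0, u * np.log(u), 0.0).sum()
    F1 = float(np.sum(u * (L + digamma_term)) + entropy - _dirichlet_kl(alpha, alpha0))
    return float(1.0 / (1.0 + np.exp(F1 - F0)))


def protected_ep(ep: np.ndarray, bor: float, K: Optional[int] = None) -> np.ndarray:
    """Blend exceedance probabilities with chance by the omnibus risk."""
    ep = np.asarray(ep, dtype=float)
    if not 0.0 <= bor <= 1.0:
        raise ValueError("bor must lie in [0, 1]")
    if K is None:
        K = len(ep)
    return (1.0 - bor) * ep + bor / K


def random_effects_bms(
    L: np.ndarray,
    labels: Optional[Sequence] = None,
    alpha0: float = 1.0,
    n_samples: int = 1_000_000,
    seed: Optional[int] = None,
) -> BMSResult:
    """Full RFX-BMS pipeline: Dirichlet fit, EP, BOR and protected EP."""
    L = _validate(L)
    n, K = L.shape
    if labels is None:
        labels = tuple(f"model_{k}" for k in range(K))
    alpha, u, n_iter = _fit_rfx_iter(L, alpha0, 1e-6, 10000)
    ep = exceedance_prob(alpha, n_samples=n_samples, seed=seed)
    bor = bayes_omnibus_risk(L, alpha, u, alpha0=alpha0)
    pxp = protected_ep(ep, bor, K)
    return BMSResult(
        labels=tuple(labels),
        dirichlet_alpha=alpha,
        expected_freq=alpha / alpha.sum(),
        ep=ep,
        bor=bor,
        pxp=pxp,
        responsibilities=u,
        n_iter=n_iter,
        n_mc_samples=n_samples if (K > 2) else 0,
        seed=seed,
    )
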