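"""Subject-level model inversion: bounded MAP estimation + Laplace evidence.

Each subject's reported belief trajectory g is fitted with a belief-update
model under flat (uniform) priors on the parameter box

    theta ~ U[0, 0.5],  alpha ~ U[0, 1],  zeta ~ U[0, 5],  sigma ~ U[1e-3, 0.5]

and a Gaussian response-noise likelihood g_t = b_t(params) + eps_t,
eps_t ~ N(0, sigma^2).  The posterior mode is located by multi-start bounded
optimisation (Latin-hypercube starts, L-BFGS-B) of the negative log joint,
and the log model evidence is approximated by Laplace's method around the
mode,

    F = -NLJ(MAP) + (d/2) log 2pi - 1/2 log det H,

with H the finite-difference Hessian of the negative log joint over the d
free dimensions (model parameters plus sigma).  Because the flat prior
densities are inside the joint, a model with more free parameters pays an
automatic Occam penalty through the prior volume, so F trades accuracy
against complexity and can be compared across models.

The user-facing surface follows the Model/Results pattern::

    model = BeliefModel(subject_trials, model="nonlinear")
    res = model.fit(seed=0)
    print(res.summary())
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import qmc

from . import _core
from .models import (
    ALPHA_BOUNDS,
    MODEL_REGISTRY,
    THETA_BOUNDS,
    ZETA_BOUNDS,
    ModelParams,
)

__all__ = [
    "FitConfig",
    "BeliefModel",
    "BeliefFitResults",
    "neg_log_joint",
    "laplace_log_evidence",
    "r_squared",
    "fit_population",
]

PARAM_BOUNDS = {"theta": THETA_BOUNDS, "alpha": ALPHA_BOUNDS, "zeta": ZETA_BOUNDS}
LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class FitConfig:
    """Knobs of the MAP + Laplace inversion.

    ``sigma_bounds`` is the support of the flat prior on the response-noise
    SD; ``n_multistarts`` Latin-hypercube start points (plus the box centre)
    guard against local optima; ``tol`` is passed to L-BFGS-B as ftol/gtol;
    ``hessian_step_frac`` scales the central-difference step as a fraction of
    each box width.
    """

    sigma_bounds: tuple[float, float] = (1e-3, 0.5)
    n_multistarts: int = 8
    tol: float = 1e-8
    hessian_step_frac: float = 1e-4
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.sigma_bounds[0] <= 0 or self.sigma_bounds[1] <= self.sigma_bounds[0]:
            raise ValueError("sigma_bounds must be a nonempty positive interval")
        if self.n_multistarts < 1:
            raise ValueError("n_multistarts must be >= 1")


def _free_bounds(model_id: str, config: FitConfig) -> tuple[list[str], np.ndarray, np.ndarray]:
    names = list(MODEL_REGISTRY[model_id]) + ["sigma"]
    lo = np.array([PARAM_BOUNDS.get(n, config.sigma_bounds)[0] for n in names])
    hi = np.array([PARAM_BOUNDS.get(n, config.sigma_bounds)[1] for n in names])
    return names, lo, hi


def _expand(x: np.ndarray, names: Sequence[str]) -> tuple[float, float, float, float]:
    d = dict(zip(names, x))
    return d.get("theta", 0.0), d.get("alpha", 0.0), d.get("zeta", 0.0), d["sigma"]


def neg_log_joint(
    params: ModelParams,
    sigma: float,
    trials: pd.DataFrame,
    config: FitConfig = FitConfig(),
) -> float:
    """Negative log joint density of data and parameters (nats).

    Gaussian negative log likelihood of the reported beliefs plus the
    negative log of the flat prior densities of the model's free parameters
    and of sigma.  Points outside the prior box get +inf (rejected).
    """
    names = list(MODEL_REGISTRY[params.model_id]) + ["sigma"]
    values = {"theta": params.theta, "alpha": params.alpha, "zeta": params.zeta, "sigma": sigma}
    for n in names:
        lo, hi = PARAM_BOUNDS.get(n, config.sigma_bounds)
        if not lo <= values[n] <= hi:
            return np.inf
    obs, belief, round_start, tone_sign = _core.pack_subject(trials)
    nll = _core.gaussian_nll(
        obs, belief, round_start, tone_sign,
        params.theta, params.alpha, params.zeta, sigma,
    )
    log_prior_vol = sum(
        np.log(PARAM_BOUNDS.get(n, config.sigma_bounds)[1] - PARAM_BOUNDS.get(n, config.sigma_bounds)[0])
        for n in names
    )
    return float(nll + log_prior_vol)


@dataclass
class BeliefFitResults:
    """MAP fit of one subject under one model.

    Attributes
    ----------
    params : pandas.Series
        MAP estimates of the free model parameters.
    sigma : float
        MAP response-noise SD.
    log_evidence : float
        Laplace approximation F to the log marginal likelihood (nats).
    rsquared : float
        Explained variance of the reported beliefs (can be negative).
    bse : pandas.Series
        Approximate posterior SDs from the inverse Hessian (free params + sigma).
    evidence_method : str
        "laplace", or "bic" when the Hessian was not positive definite.
    """

    model_id: str
    subject_id: object
    params: pd.Series
    sigma: float
    log_evidence: float
    rsquared: float
    nobs: int
    converged: bool
    bse: pd.Series
    evidence_method: str
    neg_log_joint_map: float
    model: "BeliefModel" = field(repr=False, default=None)

    @property
    def full_params(self) -> ModelParams:
        """MAP estimates embedded in a complete ModelParams (fixed values at 0)."""
        d = self.params.to_dict()
        return ModelParams(
            theta=d.get("theta", 0.0),
            alpha=d.get("alpha", 0.0),
            zeta=d.get("zeta", 0.0),
            model_id=self.model_id,
        )

    def predict(self) -> np.ndarray:
        """Predicted belief for every draw of the fitted subject, flat across rounds."""
        return self.model.predict(self.full_params)

    def summary(self) -> str:
        lines = [
            "Belief-update model inversion (MAP + Laplace)",
            "=" * 46,
            f"model:          {self.model_id}",
            f"subject:        {self.subject_id}",
            f"n observations: {self.nobs}",
            f"converged:      {self.converged}",
            f"log evidence F: {self.log_evidence:.3f} nats ({self.evidence_method})",
            f"R-squared:      {self.rsquared:.3f}",
            "-" * 46,
            f"{'param':<8}{'MAP':>10}{'approx SD':>12}",
        ]
        for name in list(self.params.index) + ["sigma"]:
            val = self.sigma if name == "sigma" else self.params[name]
            lines.append(f"{name:<8}{val:>10.4f}{self.bse[name]:>12.4f}")
        return "\n".join(lines)

    def plot_trajectory(self, ax=None):
        """Reported vs model-predicted beliefs, draw by draw."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3))
        g = self.model._belief
        ax.plot(g, "o-", ms=3, label="reported g", color="tab:green")
        ax.plot(self.predict(), "-", label=f"model b ({self.model_id})", color="tab:red")
        for s in self.model._round_start[1:-1]:
            ax.axvline(s - 0.5, color="0.8", lw=0.8)
        ax.set_xlabel("draw (rounds separated by vertical lines)")
        ax.set_ylabel("belief (1 = trout lake)")
        ax.set_ylim(-0.05, 1.05)
        ax.legend(loc="best", fontsize=8)
        return ax


class BeliefModel:
    """Belief-update model for one subject's trial table.

    Parameters
    ----------
    trials : pandas.DataFrame
        Long-format draws of a single subject with columns
        ``round, draw, tone, fish, belief`` (extra columns ignored).
    model : str
        One of ``nonlinear, linear, nonlinear_no_tone, linear_no_tone``.
    fit_config : FitConfig, optional
    """

    def __init__(self, trials: pd.DataFrame, model: str = "nonlinear",
                 fit_config: Optional[FitConfig] = None):
        if model not in MODEL_REGISTRY:
            raise ValueError(f"unknown model {model!r}")
        if "subject_id" in trials.columns and trials["subject_id"].nunique() > 1:
            raise ValueError("BeliefModel fits one subject; use fit_population for many")
        self.model_id = model
        self.config = fit_config or FitConfig()
        self.subject_id = (
            trials["subject_id"].iloc[0] if "subject_id" in trials.columns else None
        )
        self.trials = trials
        packed = _core.pack_subject(trials)
        self._obs, self._belief, self._round_start, self._tone_sign = packed
        self.nobs = len(self._obs)
        if self.nobs < 10:
            raise ValueError("need at least 10 reported beliefs to fit")

    @classmethod
    def from_dataframe(cls, trials: pd.DataFrame, subject, **kwargs) -> "BeliefModel":
        """Select ``subject`` from a multi-subject trial table and build the model."""
        sub = trials[trials["subject_id"] == subject]
        if sub.empty:
            raise KeyError(f"subject {subject!r} not in trial table")
        return cls(sub, **kwargs)

    # -- likelihood machinery -------------------------------------------------

    def predict(self, params: ModelParams) -> np.ndarray:
        return _core.trajectory_flat(
            self._obs, self._round_start, self._tone_sign,
            params.theta, params.alpha, params.zeta,
        )

    def _objective(self, x: np.ndarray, names: Sequence[str], log_prior_vol: float) -> float:
        theta, alpha, zeta, sigma = _expand(x, names)
        nll = _core.gaussian_nll(
            self._obs, self._belief, self._round_start, self._tone_sign,
            theta, alpha, zeta, sigma,
        )
        return nll + log_prior_vol

    def fit(self, seed: Optional[int] = None) -> BeliefFitResults:
        """Multi-start bounded MAP fit; deterministic for a given seed."""
        cfg = self.config
        if seed is None:
            seed = cfg.seed
        names, lo, hi = _free_bounds(self.model_id, cfg)
        d = len(names)
        log_prior_vol = float(np.sum(np.log(hi - lo)))

        sampler = qmc.LatinHypercube(d=d, seed=seed)
        starts = qmc.scale(sampler.random(cfg.n_multistarts), lo, hi)
        starts = np.vstack([starts, 0.5 * (lo + hi)])

        best = None
        any_ok = False
        for x0 in starts:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = optimize.minimize(
                    self._objective, x0, args=(names, log_prior_vol),
                    method="L-BFGS-B", bounds=list(zip(lo, hi)),
                    options={"ftol": cfg.tol, "gtol": cfg.tol, "maxiter": 500},
                )
            any_ok = any_ok or res.success
            if best is None or res.fun < best.fun:
                best = res

        x_map = np.clip(best.x, lo, hi)
        theta, alpha, zeta, sigma = _expand(x_map, names)
        nlj_map = float(best.fun)

        H = self._hessian(x_map, names, log_prior_vol, lo, hi)
        F, method, bse = self._evidence_from_hessian(nlj_map, H, d)
        param_names = names[:-1]
        params = pd.Series(dict(zip(names, x_map)))[param_names]

        return BeliefFitResults(
            model_id=self.model_id,
            subject_id=self.subject_id,
            params=params,
            sigma=float(sigma),
            log_evidence=F,
            rsquared=self._rsquared(x_map, names),
            nobs=self.nobs,
            converged=bool(any_ok and np.isfinite(nlj_map)),
            bse=pd.Series(bse, index=names),
            evidence_method=method,
            neg_log_joint_map=nlj_map,
            model=self,
        )

    def _hessian(self, x, names, log_prior_vol, lo, hi) -> np.ndarray:
        """Central-difference Hessian on the smooth extension of the log joint.

        The flat priors are constant, so just outside the box the objective is
        the (well-defined) Gaussian NLL; evaluating there lets boundary MAPs
        keep a symmetric stencil.
        """
        d = len(x)
        h = self.config.hessian_step_frac * (hi - lo)
        f0 = self._objective(x, names, log_prior_vol)
        H = np.empty((d, d))
        for i in range(d):
            ei = np.zeros(d); ei[i] = h[i]
            fpp = self._objective(x + ei, names, log_prior_vol)
            fmm = self._objective(x - ei, names, log_prior_vol)
            H[i, i] = (fpp - 2 * f0 + fmm) / h[i] ** 2
            for j in range(i + 1, d):
                ej = np.zeros(d); ej[j] = h[j]
                fpq = self._objective(x + ei + ej, names, log_prior_vol)
                fpm = self._objective(x + ei - ej, names, log_prior_vol)
                fmp = self._objective(x - ei + ej, names, log_prior_vol)
                fmq = self._objective(x - ei - ej, names, log_prior_vol)
                H[i, j] = H[j, i] = (fpq - fpm - fmp + fmq) / (4 * h[i] * h[j])
        return H

    def _evidence_from_hessian(self, nlj_map, H, d):
        eigvals = np.linalg.eigvalsh(H)
        if np.all(eigvals > 0):
            sign, logdet = np.linalg.slogdet(H)
            F = -nlj_map + 0.5 * d * LOG_2PI - 0.5 * logdet
            bse = np.sqrt(np.diag(np.linalg.inv(H)))
            return float(F), "laplace", bse
        # curvature degenerate (e.g. flat direction at a box face): BIC-style
        F = -nlj_map + 0.5 * d * LOG_2PI - 0.5 * d * np.log(self.nobs)
        return float(F), "bic", np.full(d, np.nan)

    def _rsquared(self, x, names) -> float:
        theta, alpha, zeta, _ = _expand(x, names)
        pred = _core.trajectory_flat(
            self._obs, self._round_start, self._tone_sign, theta, alpha, zeta
        )
        return _r2(self._belief, pred)


def _r2(g: np.ndarray, pred: np.ndarray) -> float:
    ss_tot = float(np.sum((g - g.mean()) ** 2))
    if len(g) < 2 or ss_tot == 0.0:
        raise ValueError("R^2 undefined: fewer than 2 reports or zero variance")
    ss_res = float(np.sum((g - pred) ** 2))
    return 1.0 - ss_res / ss_tot


def r_squared(fit: BeliefFitResults, trials: Optional[pd.DataFrame] = None) -> float:
    """Explained variance of the reported beliefs under the MAP trajectory.

    ``trials`` defaults to the table the fit was built from; passing a
    different table of the same subject re-scores the MAP parameters on it.
    """
    if trials is None:
        return fit.rsquared
    obs, belief, round_start, tone_sign = _core.pack_subject(trials)
    p = fit.full_params
    pred = _core.trajectory_flat(obs, round_start, tone_sign, p.theta, p.alpha, p.zeta)
    return _r2(belief, pred)


def laplace_log_evidence(fit: BeliefFitResults, trials: Optional[pd.DataFrame] = None) -> float:
    """Laplace log evidence of a converged fit (recomputed if trials given)."""
    if not fit.converged:
        raise ValueError("log evidence requires a converged fit")
    if trials is None:
        return fit.log_evidence
    model = BeliefModel(trials, model=fit.model_id, fit_config=fit.model.config)
    names, lo, hi = _free_bounds(fit.model_id, model.config)
    x = np.array([fit.params.get(n, fit.sigma) if n != "sigma" else fit.sigma for n in names])
    log_prior_vol = float(np.sum(np.log(hi - lo)))
    nlj = model._objective(x, names, log_prior_vol)
    H = model._hessian(x, names, log_prior_vol, lo, hi)
    F, _, _ = model._evidence_from_hessian(nlj, H, len(names))
    return F


def fit_population(
    trials: pd.DataFrame,
    models: Sequence[str] = ("nonlinear", "linear"),
    fit_config: Optional[FitConfig] = None,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Fit every subject in a multi-subject trial table with each model.

    Returns one row per subject x model with MAP parameters, sigma, log
    evidence F, R² and diagnostics (the fits.csv layout).  Per-subject seeds
    are derived deterministically from ``seed``.
    """
    rows = []
    subjects = trials["subject_id"].unique()
    ss = np.random.SeedSequence(seed)
    subject_seeds = ss.generate_state(len(subjects)) % (2**31)
    for subj, s_seed in zip(subjects, subject_seeds):
        sub = trials[trials["subject_id"] == subj]
        for model_id in models:
            res = BeliefModel(sub, model=model_id, fit_config=fit_config).fit(seed=int(s_seed))
            rows.append(
                {
                    "subject_id": subj,
                    "model": model_id,
                    "theta": res.params.get("theta", 0.0),
                    "alpha": res.params.get("alpha", 0.0),
                    "zeta": res.params.get("zeta", 0.0),
                    "sigma": res.sigma,
                    "log_evidence": res.log_evidence,
                    "r_squared": res.rsquared,
                    "n_obs": res.nobs,
                    "converged": res.converged,
                    "evidence_method": res.evidence_method,
                }
            )
    return pd.DataFrame(rows)
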