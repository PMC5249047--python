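"""Synthetic populations of belief-updating agents.

Because no human dataset accompanies the task, every pipeline stage is
exercised on simulated agents.  An agent carries the generative parameters
(theta, alpha, zeta), a per-subject commit threshold tau, and Gaussian
response noise; it performs the fish-lake task draw by draw: tone-shifted
prior belief, non-linear prediction-error updates, a noisy clipped report
g = clip(b + eps, 0, 1), and commitment as soon as the reported confidence
|g - 0.5| reaches tau (or a hard draw cap).  Psychosis-proneness scores
(PDI-like and CAPS-like totals) are attached through a Gaussian copula so
that they are negatively rank-correlated with the agent's true zeta and
mutually correlated, with right-skewed negative-binomial marginals.

The defaults encode the emulated study population: 94 subjects, 30 rounds,
zeta centred on 3.44 with >95% of mass between roughly 2.5 and 4, response
noise SD 0.05, and a score--zeta rank correlation of -0.25.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .models import ModelParams, initial_belief, update_nonlinear
from .task import TaskConfig, generate_rounds, draw_fish

__all__ = [
    "PopulationConfig",
    "SyntheticDataset",
    "sample_population",
    "simulate_subject",
    "attach_scores",
    "generate_dataset",
]

TRIAL_COLUMNS = [
    "subject_id", "round", "draw", "tone", "fish", "belief", "committed", "final_choice",
]


@dataclass(frozen=True)
class PopulationConfig:
    """Generative population for synthetic agents.

    Parameter marginals are truncated normals (mean, sd) on the model's
    prior boxes; ``tau_range`` is the uniform support of the per-subject
    commit threshold on reported confidence |g - 0.5|; ``score_coupling``
    is the target rank correlation between true zeta and each score and
    ``score_corr`` the rank correlation between the two scores themselves.
    ``score_means`` set the negative-binomial marginal means of the
    PDI-like and CAPS-like totals.
    """

    n_subjects: int = 94
    theta_dist: tuple[float, float] = (0.25, 0.10)
    alpha_dist: tuple[float, float] = (0.60, 0.15)
    zeta_dist: tuple[float, float] = (3.44, 0.35)
    noise_sd: float = 0.05
    tau_range: tuple[float, float] = (0.25, 0.45)
    score_coupling: float = -0.25
    score_corr: float = 0.70
    score_means: tuple[float, float] = (64.5, 30.4)
    score_dispersions: tuple[float, float] = (2.0, 1.2)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not abs(self.score_coupling) < 1:
            raise ValueError("|score_coupling| must be < 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class SyntheticDataset:
    """Complete synthetic study: trial table, subject table, manifest."""

    trials: pd.DataFrame
    subjects: pd.DataFrame
    manifest: dict

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.trials.to_csv(outdir / "trials.csv", index=False)
        self.subjects.to_csv(outdir / "subjects.csv", index=False)
        (outdir / "manifest.json").write_text(json.dumps(self.manifest, indent=2))

    @classmethod
    def read(cls, outdir) -> "SyntheticDataset":
        outdir = Path(outdir)
        trials = pd.read_csv(outdir / "trials.csv")
        trials["final_choice"] = trials["final_choice"].where(trials["committed"], None)
        subjects = pd.read_csv(outdir / "subjects.csv")
        manifest = json.loads((outdir / "manifest.json").read_text())
        return cls(trials=trials, subjects=subjects, manifest=manifest)


def _truncnorm(mean: float, sd: float, lo: float, hi: float):
    if sd == 0:
        return None  # degenerate: caller returns the mean
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return sps.truncnorm(a, b, loc=mean, scale=sd)


def sample_population(config: PopulationConfig,
                      rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Draw i.i.d. subject-level parameters and commit thresholds."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    cols = {"subject_id": [f"S{i:04d}" for i in range(1, n + 1)]}
    for name, (mean, sd), (lo, hi) in [
        ("theta", config.theta_dist, (0.0, 0.5)),
        ("alpha", config.alpha_dist, (0.0, 1.0)),
        ("zeta", config.zeta_dist, (0.0, 5.0)),
    ]:
        dist = _truncnorm(mean, sd, lo, hi)
        cols[name] = np.full(n, mean) if dist is None else dist.rvs(size=n, random_state=rng)
    lo, hi = config.tau_range
    cols["tau"] = rng.uniform(lo, hi, size=n)
    return pd.DataFrame(cols)


def simulate_subject(
    params: ModelParams,
    tau: float,
    noise_sd: float,
    task_config: TaskConfig,
    rng: np.random.Generator,
    subject_id: str = "S0001",
    rounds=None,
) -> pd.DataFrame:
    """Simulate one agent through all rounds of the task.

    Per round: tone-shifted initial belief, then repeatedly angle a fish,
    update the belief with the non-linear rule (which at zeta=0 is the
    linear rule), report g = clip(b + noise, 0, 1), and commit as soon as
    |g - 0.5| >= tau or the draw cap is reached.  The final choice is the
    lake on the reported side of 0.5 (trout iff g >= 0.5).  ``rounds`` may
    supply a pre-generated round structure; by default fresh rounds are
    drawn from ``rng``.
    """
    if rounds is None:
        rounds = generate_rounds(task_config, rng)
    rows = []
    for rnd in rounds:
        b = initial_belief(params.theta, rnd.tone)
        for draw in range(1, task_config.max_draws_per_round + 1):
            o = draw_fish(rnd, task_config, rng)
            b = update_nonlinear(b, o, params.alpha, params.zeta)
            g = float(np.clip(b + rng.normal(0.0, noise_sd) if noise_sd > 0 else b, 0.0, 1.0))
            commit = abs(g - 0.5) >= tau or draw == task_config.max_draws_per_round
            rows.append(
                {
                    "subject_id": subject_id,
                    "round": rnd.round_index,
                    "draw": draw,
                    "tone": rnd.tone,
                    "fish": o,
                    "belief": g,
                    "committed": commit,
                    "final_choice": ("trout" if g >= 0.5 else "carp") if commit else None,
                }
            )
            if commit:
                break
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def attach_scores(
    subjects: pd.DataFrame,
    coupling: float = -0.25,
    rng: Optional[np.random.Generator] = None,
    score_corr: float = 0.70,
    score_means: tuple[float, float] = (64.5, 30.4),
    score_dispersions: tuple[float, float] = (2.0, 1.2),
) -> pd.DataFrame:
    """Attach PDI-like and CAPS-like totals rank-correlated with true zeta.

    A Gaussian copula ties the scores' latent normals to the normal scores
    of the subjects' zeta ranks; target Spearman correlations are converted
    to latent Pearson correlations via rho_latent = 2 sin(pi * rho_S / 6).
    The latent normals are then pushed through negative-binomial quantile
    functions, giving right-skewed positive-integer totals.
    """
    if rng is None:
        rng = np.random.default_rng()
    if not abs(coupling) < 1:
        raise ValueError("|coupling| must be < 1")
    n = len(subjects)
    out = subjects.copy()

    def latent(rho_s: float) -> float:
        return 2.0 * np.sin(np.pi * rho_s / 6.0)

    rc = latent(coupling)
    r12 = latent(score_corr)
    # joint feasibility: both scores coupled at rc to zeta forces their mutual
    # latent correlation to be at least 2*rc^2 - 1; clamp up at strong coupling
    r12 = max(r12, 2.0 * rc**2 - 1.0 + 1e-9)
    # latent correlation matrix over (z_zeta, z_pdi, z_caps)
    C = np.array([[1.0, rc, rc], [rc, 1.0, r12], [rc, r12, 1.0]])
    # normal scores of the observed zeta ranks anchor the copula to the data
    ranks = sps.rankdata(out["zeta"].to_numpy(), method="average")
    z_zeta = sps.norm.ppf((ranks - 0.5) / n)
    # conditional distribution of (z_pdi, z_caps) | z_zeta
    c12 = C[0, 1:]
    cond_cov = C[1:, 1:] - np.outer(c12, c12)
    chol = np.linalg.cholesky(cond_cov)
    eps = rng.standard_normal((n, 2)) @ chol.T
    z_scores = np.outer(z_zeta, c12) + eps
    u = sps.norm.cdf(z_scores)
    for j, name in enumerate(["pdi_score", "caps_score"]):
        mean, r = score_means[j], score_dispersions[j]
        p = r / (r + mean)
        out[name] = sps.nbinom.ppf(u[:, j], r, p).astype(int)
    return out


def generate_dataset(
    pop_config: PopulationConfig = PopulationConfig(),
    task_config: TaskConfig = TaskConfig(),
    outdir=None,
    seed: Optional[int] = None,
) -> SyntheticDataset:
    """Sample a population, run every agent through the task, attach scores.

    ``seed`` overrides ``pop_config.seed``; per-subject RNG streams are
    spawned from one SeedSequence so the dataset is reproducible as a whole.
    Writes trials.csv, subjects.csv and manifest.json when ``outdir`` given.
    """
    if seed is None:
        seed = pop_config.seed
    ss = np.random.SeedSequence(seed)
    rng_pop, rng_scores, rng_task = (np.random.default_rng(s) for s in ss.spawn(3))

    subjects = sample_population(pop_config, rng_pop)
    subjects = attach_scores(
        subjects,
        coupling=pop_config.score_coupling,
        rng=rng_scores,
        score_corr=pop_config.score_corr,
        score_means=pop_config.score_means,
        score_dispersions=pop_config.score_dispersions,
    )
    frames = []
    error_rates = []
    for row, child in zip(subjects.itertuples(index=False), rng_task.spawn(len(subjects))):
        params = ModelParams(theta=row.theta, alpha=row.alpha, zeta=row.zeta,
                             model_id="nonlinear")
        rounds = generate_rounds(task_config, child)
        t = simulate_subject(params, row.tau, pop_config.noise_sd, task_config,
                             child, subject_id=row.subject_id, rounds=rounds)
        frames.append(t)
        true_lake = {r.round_index: r.true_lake for r in rounds}
        commits = t[t["committed"]]
        wrong = [
            choice != true_lake[rnd]
            for rnd, choice in zip(commits["round"], commits["final_choice"])
        ]
        error_rates.append(float(np.mean(wrong)))
    trials = pd.concat(frames, ignore_index=True)
    subjects = subjects.assign(error_rate=error_rates)

    manifest = {
        "population_config": _jsonable(asdict(pop_config)),
        "task_config": _jsonable(asdict(task_config)),
        "seed": seed,
        "n_trials": int(len(trials)),
    }
    ds = SyntheticDataset(trials=trials, subjects=subjects, manifest=manifest)
    if outdir is not None:
        ds.write(outdir)
    return ds


def _jsonable(d: dict) -> dict:
    return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
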