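"""Behavioural and correlational statistics.

Covers the downstream analysis chain: draws-to-decision and the
jumping-to-conclusions (JTC) split, Mann–Whitney group comparisons, Spearman
and partial Spearman rank correlations between fitted parameters and
psychosis-proneness scores, one-sample Kolmogorov–Smirnov distribution tests
for the non-linearity parameter, a Šidák-type multiplicity adjustment for
correlated outcomes, and the error-rate exclusion / low-ζ outlier
sensitivity rules.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats as sps

__all__ = [
    "exclusion_filter",
    "draws_to_decision",
    "jtc_split",
    "mann_whitney_u",
    "spearman",
    "partial_spearman",
    "ks_test",
    "adjust_correlated_p",
    "outlier_sensitivity",
    "kolmogorov_sf",
    "analyze_dataset",
]


# ---------------------------------------------------------------------------
# subject summaries and filters
# ---------------------------------------------------------------------------

def draws_to_decision(trials: pd.DataFrame) -> pd.Series:
    """Mean number of draws before commitment, per subject.

    ``trials`` is a long-format multi-subject table; every (subject, round)
    must contain exactly one committed draw, which by task construction is
    the round's last draw.
    """
    commits = trials[trials["committed"].astype(bool)]
    n_rounds = trials.groupby("subject_id")["round"].nunique()
    n_commits = commits.groupby("subject_id")["round"].nunique()
    if not n_rounds.equals(n_commits.reindex(n_rounds.index).fillna(0).astype(n_rounds.dtype)):
        bad = n_rounds.index[n_rounds != n_commits.reindex(n_rounds.index).fillna(0)]
        raise ValueError(f"rounds without a committed draw for subjects {list(bad)}")
    return commits.groupby("subject_id")["draw"].mean().rename("mean_draws_to_decision")


def exclusion_filter(summaries: pd.DataFrame, column: str = "error_rate"):
    """Exclude subjects whose error rate exceeds mean + 2 SD of the sample.

    The threshold is computed once on the full sample (no iteration).
    Returns ``(kept, excluded)`` DataFrames; with a single subject the SD is
    undefined and nobody is excluded.
    """
    x = summaries[column].to_numpy(dtype=float)
    if len(x) < 2:
        return summaries.copy(), summaries.iloc[0:0].copy()
    cut = x.mean() + 2.0 * x.std(ddof=1)
    mask = x > cut
    return summaries[~mask].copy(), summaries[mask].copy()


def jtc_split(summaries: pd.DataFrame, rule: str = "quartile",
              column: str = "mean_draws_to_decision") -> pd.Series:
    """Label subjects as jumping-to-conclusions (True) or not.

    ``rule="quartile"``: JTC = subjects at or below the lowest quartile of
    mean draws to decision (type-7 quantile; ties at the cutoff are JTC).
    ``rule="fixed"``: the classic criterion of <= 2 draws to decision.
    """
    x = summaries[column].to_numpy(dtype=float)
    if rule == "quartile":
        if len(x) < 4:
            raise ValueError("quartile rule needs >= 4 subjects")
        cutoff = float(np.quantile(x, 0.25))
    elif rule == "fixed":
        cutoff = 2.0
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return pd.Series(x <= cutoff, index=summaries.index, name="jtc")


# ---------------------------------------------------------------------------
# tests and correlations
# ---------------------------------------------------------------------------

def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann–Whitney test; returns (U, p).

    U is reported for the first sample (U_a counts pairs where a beats b;
    the complementary convention is U_b = n_a*n_b - U_a).  Small samples
    (n_a*n_b <= 400, no ties) use exact enumeration; otherwise the
    tie-corrected normal approximation.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) * len(b) <= 400 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Spearman rank correlation (rho, p), t-approximation with n-2 df."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 4:
        raise ValueError("need n >= 4")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input")
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def partial_spearman(x, y, z) -> tuple[float, float]:
    """Spearman partial correlation of x and y controlling for z.

    All three variables are average-ranked; the Pearson partial correlation
    of the ranked x and y given ranked z is returned with a two-sided p from
    t = r*sqrt((n-3)/(1-r^2)) on n-3 degrees of freedom.
    """
    x, y, z = (np.asarray(v, float) for v in (x, y, z))
    n = len(x)
    if n < 5:
        raise ValueError("need n >= 5")
    rx, ry, rz = (sps.rankdata(v) for v in (x, y, z))
    r_xy = np.corrcoef(rx, ry)[0, 1]
    r_xz = np.corrcoef(rx, rz)[0, 1]
    r_yz = np.corrcoef(ry, rz)[0, 1]
    denom = (1 - r_xz**2) * (1 - r_yz**2)
    if denom <= 1e-12:
        raise ValueError("covariate collinear with x or y: partial correlation undefined")
    r = (r_xy - r_xz * r_yz) / np.sqrt(denom)
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 3) / (1 - r**2))
    p = 2.0 * sps.t.sf(abs(t), df=n - 3)
    return r, float(p)


def kolmogorov_sf(z: float) -> float:
    """Asymptotic Kolmogorov law Q(z) = 2 sum_{k>=1} (-1)^{k-1} exp(-2 k^2 z^2)."""
    return float(special.kolmogorov(z))


def ks_test(values: Sequence[float], reference, args: tuple = ()) -> tuple[float, float, float]:
    """One-sample Kolmogorov–Smirnov test against a named reference.

    ``reference="uniform"`` with ``args=(a, b)`` tests against U(a, b);
    ``reference="normal"`` against N(mean, sd) with the parameters estimated
    from the sample (no small-sample/Lilliefors correction — the classic
    asymptotic law is applied to the estimated-parameter statistic).
    Returns (D, Z, p) with Z = sqrt(n) * D and p = Q(Z).
    """
    values = np.asarray(values, float)
    n = len(values)
    if n < 5:
        raise ValueError("need n >= 5")
    if reference == "uniform":
        a, b = args if args else (0.0, 1.0)
        cdf = sps.uniform(loc=a, scale=b - a).cdf
    elif reference == "normal":
        mu, sd = args if args else (values.mean(), values.std(ddof=1))
        cdf = sps.norm(loc=mu, scale=sd).cdf
    else:
        raise ValueError(f"unknown reference {reference!r}")
    d = float(sps.kstest(values, cdf).statistic)
    z = float(np.sqrt(n) * d)
    return d, z, kolmogorov_sf(z)


def adjust_correlated_p(p_raw, m: int = 2, rbar: float = 0.0):
    """Šidák-type adjustment for m tests with mean inter-outcome correlation rbar.

    p_adj = 1 - (1 - p)^(m^(1 - rbar)).  At rbar=0 this is the ordinary
    Šidák correction for m independent tests; at rbar=1 (perfectly redundant
    outcomes) no correction is applied.
    """
    p = np.asarray(p_raw, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0.0 <= rbar <= 1.0:
        raise ValueError("rbar must lie in [0, 1]")
    m_eff = m ** (1.0 - rbar)
    out = 1.0 - (1.0 - p) ** m_eff
    return float(out) if np.isscalar(p_raw) else out


def outlier_sensitivity(x, y, n_sd: float = 2.0) -> dict:
    """Spearman correlation with and without low-x outliers.

    Outliers are values of ``x`` more than ``n_sd`` SDs *below* the sample
    mean (the rule used for screening implausibly small non-linearity
    estimates).  Returns the primary and excluded-rerun results with the
    cutoff and outlier count; degenerate (zero-SD) samples flag no outliers.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 10:
        raise ValueError("need n >= 10")
    sd = x.std(ddof=1)
    cutoff = x.mean() - n_sd * sd
    mask = x < cutoff
    rho, p = spearman(x, y)
    out = {
        "cutoff": float(cutoff),
        "n_outliers": int(mask.sum()),
        "outlier_index": np.flatnonzero(mask).tolist(),
        "primary": {"rho": rho, "p": p, "n": len(x)},
        "degenerate": bool(sd == 0),
    }
    if mask.any():
        rho2, p2 = spearman(x[~mask], y[~mask])
        out["excluded_rerun"] = {"rho": rho2, "p": p2, "n": int((~mask).sum())}
    else:
        out["excluded_rerun"] = dict(out["primary"])
    return out


# ---------------------------------------------------------------------------
# full behavioural report
# ---------------------------------------------------------------------------

def analyze_dataset(
    subjects: pd.DataFrame,
    trials: pd.DataFrame,
    fits: pd.DataFrame,
    nonlinear_model: str = "nonlinear",
    linear_model: str = "linear",
    rbar: Optional[float] = None,
) -> dict:
    """Run the complete behavioural/correlational analysis chain.

    ``subjects`` must carry pdi_score and caps_score columns, ``fits`` the
    per-subject x model parameter table from :func:`fit_population`.  The
    mean inter-outcome correlation ``rbar`` for the multiplicity adjustment
    defaults to the observed Spearman correlation between the two scores.
    Returns a nested dict (JSON-ready) mirroring the analysis structure:
    JTC group tests, score correlations with draws-to-decision and with the
    non-linearity parameter (raw, adjusted, partial, outlier-screened), and
    KS tests on the fitted non-linearity values.
    """
    dtd = draws_to_decision(trials)
    summ = subjects.set_index("subject_id").join(dtd)
    nl = fits[fits["model"] == nonlinear_model].set_index("subject_id")
    lin = fits[fits["model"] == linear_model].set_index("subject_id")
    summ["zeta_hat"] = nl["zeta"]
    summ["alpha_linear_hat"] = lin["alpha"]
    summ = summ.dropna(subset=["mean_draws_to_decision", "zeta_hat"])

    if rbar is None:
        rbar, _ = spearman(summ["pdi_score"], summ["caps_score"])
        rbar = abs(float(rbar))

    jtc = jtc_split(summ.reset_index(), rule="quartile").to_numpy()
    report: dict = {"n_subjects": int(len(summ)), "rbar": rbar}

    # score normality screens (motivating the non-parametric tests)
    report["score_distribution"] = {}
    for score in ("pdi_score", "caps_score"):
        d, z, p = ks_test(summ[score], "normal")
        report["score_distribution"][score] = {"D": d, "Z": z, "p": p}

    # categorical JTC analysis
    report["jtc_group"] = {"n_jtc": int(jtc.sum()), "n_no_jtc": int((~jtc).sum())}
    p_cat = {}
    for score in ("pdi_score", "caps_score"):
        u, p = mann_whitney_u(summ.loc[jtc, score], summ.loc[~jtc, score])
        report["jtc_group"][score] = {
            "U": u,
            "p": p,
            "median_jtc": float(summ.loc[jtc, score].median()),
            "median_no_jtc": float(summ.loc[~jtc, score].median()),
        }
        p_cat[score] = p
    for score in ("pdi_score", "caps_score"):
        report["jtc_group"][score]["p_adjusted"] = adjust_correlated_p(
            p_cat[score], m=2, rbar=rbar
        )

    # correlational JTC analysis
    report["jtc_correlational"] = {}
    for score in ("pdi_score", "caps_score"):
        rho, p = spearman(summ["mean_draws_to_decision"], summ[score])
        report["jtc_correlational"][score] = {
            "rho": rho, "p": p,
            "p_adjusted": adjust_correlated_p(p, m=2, rbar=rbar),
        }

    # distribution of the fitted non-linearity parameter
    zeta = summ["zeta_hat"].to_numpy()
    report["zeta_distribution"] = {"mean": float(zeta.mean()), "sd": float(zeta.std(ddof=1))}
    d, z, p = ks_test(zeta, "uniform", args=(0.0, 5.0))
    report["zeta_distribution"]["vs_uniform_prior"] = {"D": d, "Z": z, "p": p}
    d, z, p = ks_test(zeta, "normal")
    report["zeta_distribution"]["vs_normal"] = {"D": d, "Z": z, "p": p}

    # zeta as a JTC account
    r_dtd = sps.pearsonr(zeta, summ["mean_draws_to_decision"])
    report["zeta_vs_draws"] = {"r": float(r_dtd.statistic), "p": float(r_dtd.pvalue)}

    # correlations with psychosis-proneness, partial and outlier-screened
    report["zeta_vs_scores"] = {}
    for score in ("pdi_score", "caps_score"):
        rho, p = spearman(zeta, summ[score])
        pr, pp = partial_spearman(zeta, summ[score], summ["alpha_linear_hat"])
        sens = outlier_sensitivity(zeta, summ[score].to_numpy())
        report["zeta_vs_scores"][score] = {
            "rho": rho,
            "p": p,
            "p_adjusted": adjust_correlated_p(p, m=2, rbar=rbar),
            "partial_rho_given_alpha": pr,
            "partial_p": pp,
            "outlier_sensitivity": sens,
        }
    return report


def report_markdown(report: dict) -> str:
    """Render :func:`analyze_dataset` output as a readable markdown report."""
    L = ["# Behavioural analysis report", ""]
    L.append(f"Subjects analysed: {report['n_subjects']}  (r̄ = {report['rbar']:.3f})")
    L.append("")
    L.append("## Score distributions (one-sample KS vs fitted normal)")
    for s, r in report["score_distribution"].items():
        L.append(f"- {s}: Z = {r['Z']:.3f}, p = {r['p']:.3f}")
    g = report["jtc_group"]
    L.append("")
    L.append(f"## JTC group comparison (n_JTC = {g['n_jtc']}, n_noJTC = {g['n_no_jtc']})")
    for s in ("pdi_score", "caps_score"):
        r = g[s]
        L.append(
            f"- {s}: U = {r['U']:.1f}, p = {r['p']:.3f} (adjusted {r['p_adjusted']:.3f}); "
            f"medians {r['median_jtc']:.1f} vs {r['median_no_jtc']:.1f}"
        )
    L.append("")
    L.append("## Draws-to-decision correlations")
    for s, r in report["jtc_correlational"].items():
        L.append(f"- {s}: rho = {r['rho']:.3f}, p = {r['p']:.3f} (adjusted {r['p_adjusted']:.3f})")
    zd = report["zeta_distribution"]
    L.append("")
    L.append(f"## Non-linearity parameter (mean {zd['mean']:.2f}, SD {zd['sd']:.2f})")
    L.append(f"- vs uniform prior: Z = {zd['vs_uniform_prior']['Z']:.3f}, p = {zd['vs_uniform_prior']['p']:.3g}")
    L.append(f"- vs normal: Z = {zd['vs_normal']['Z']:.3f}, p = {zd['vs_normal']['p']:.3f}")
    L.append(f"- vs draws to decision: r = {report['zeta_vs_draws']['r']:.3f}, p = {report['zeta_vs_draws']['p']:.3g}")
    L.append("")
    L.append("## Non-linearity vs psychosis-proneness scores")
    for s, r in report["zeta_vs_scores"].items():
        sens = r["outlier_sensitivity"]
        L.append(
            f"- {s}: rho = {r['rho']:.3f}, p = {r['p']:.3f} (adjusted {r['p_adjusted']:.3f}); "
            f"partial rho | alpha = {r['partial_rho_given_alpha']:.3f} (p = {r['partial_p']:.3f}); "
            f"without {sens['n_outliers']} low-ζ outliers: rho = {sens['excluded_rerun']['rho']:.3f}"
        )
    L.append("")
    return "\n".join(L)
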