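"""Inferential layer: paired t, JZS Bayes factors, GG RM-ANOVA, contrasts.

The units of analysis are typically the saliency models themselves (each
model yields one score per stratum), so the paired tests treat models as
subjects. Effect size for the paired t is Cohen's d = t / sqrt(n), i.e.
the mean difference in units of the SD of differences. Bayes factors use
the default JZS (Jeffreys-Zellner-Siow) prior: a Cauchy prior with scale
r = sqrt(2)/2 on the standardised effect size, integrated numerically.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import integrate, stats

__all__ = [
    "PairedTestResult",
    "RmAnovaResult",
    "paired_t",
    "jzs_bf10",
    "rm_anova_gg",
    "bonferroni_contrasts",
]


class DegenerateDataError(ValueError):
    """Raised when the data have no variance where some is required."""


@dataclass
class PairedTestResult:
    t: float
    df: int
    p: float
    cohens_d: float
    ci_low: float
    ci_high: float
    bf10: float
    n: int


@dataclass
class RmAnovaResult:
    F: float
    df1: float
    df2: float
    epsilon_gg: float
    p: float
    eta_sq: float


def paired_t(x, y, compute_bf: bool = True) -> PairedTestResult:
    """Two-sided paired t-test on x - y with effect size, CI and BF10."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("all pairwise differences are identical")
    se = sd / np.sqrt(n)
    t = float(d.mean() / se)
    df = n - 1
    p = float(2 * stats.t.sf(abs(t), df))
    tcrit = stats.t.ppf(0.975, df)
    bf = jzs_bf10(t, n) if compute_bf else float("nan")
    return PairedTestResult(
        t=t,
        df=df,
        p=p,
        cohens_d=t / np.sqrt(n),
        ci_low=float(d.mean() - tcrit * se),
        ci_high=float(d.mean() + tcrit * se),
        bf10=bf,
        n=n,
    )


def jzs_bf10(t: float, n: int, r: float = np.sqrt(2) / 2) -> float:
    """Default-prior JZS Bayes factor for a one-sample/paired t design.

    BF10 = integral over delta of the noncentral-t likelihood of the
    observed t under effect size delta, weighted by a Cauchy(0, r) prior,
    divided by the central-t likelihood under the null. Depends on the
    data only through (t, n).
    """
    if n < 2:
        raise ValueError("need at least 2 observations")
    if r <= 0:
        raise ValueError("prior scale must be positive")
    nu = n - 1
    sqrt_n = np.sqrt(n)

    def integrand(delta: float) -> float:
        return stats.nct.pdf(t, nu, delta * sqrt_n) * stats.cauchy.pdf(delta, 0.0, r)

    # split at 0 and around the maximum-likelihood effect size for stable
    # quadrature at large |t|
    d_hat = t / sqrt_n
    breaks = [-np.inf] + sorted({0.0, d_hat}) + [np.inf]
    marginal = 0.0
    err = 0.0
    for a, b in zip(breaks, breaks[1:]):
        part, part_err = integrate.quad(integrand, a, b, limit=200)
        marginal += part
        err += part_err
    null_like = stats.t.pdf(t, nu)
    if not np.isfinite(marginal) or marginal <= 0 or null_like <= 0:
        raise ArithmeticError(
            f"Bayes factor quadrature failed (marginal={marginal}, err={err}, t={t}, n={n})"
        )
    return float(marginal / null_like)


def rm_anova_gg(scores: np.ndarray | pd.DataFrame) -> RmAnovaResult:
    """One-way within-subjects ANOVA with Greenhouse-Geisser correction.

    ``scores`` is subjects x conditions (e.g. models x age bins). The GG
    epsilon is estimated from the sample covariance of the within-subject
    scores; corrected degrees of freedom are df1 = eps*(k-1) and
    df2 = eps*(k-1)*(n-1). Effect size is partial eta squared
    SS_cond / (SS_cond + SS_error) (equal to classical eta squared for a
    single within factor's effect-vs-error decomposition).
    """
    a = np.asarray(scores, dtype=float)
    if a.ndim != 2 or a.shape[0] < 2 or a.shape[1] < 2:
        raise ValueError("scores must be a subjects x conditions matrix, both >= 2")
    n, k = a.shape
    grand = a.mean()
    cond_means = a.mean(axis=0)
    subj_means = a.mean(axis=1)
    ss_cond = n * np.sum((cond_means - grand) ** 2)
    ss_subj = k * np.sum((subj_means - grand) ** 2)
    ss_tot = np.sum((a - grand) ** 2)
    ss_err = ss_tot - ss_cond - ss_subj
    if ss_tot == 0:
        raise DegenerateDataError("constant score matrix")
    ms_cond = ss_cond / (k - 1)
    ms_err = ss_err / ((k - 1) * (n - 1))
    if ms_err == 0:
        if ss_cond == 0:  # e.g. identical conditions, varying subjects
            ms_cond = 0.0
            ms_err = 1.0
        else:
            raise DegenerateDataError("zero error variance with a condition effect")
    F = float(ms_cond / ms_err)

    S = np.cov(a, rowvar=False)  # k x k sample covariance over subjects
    row = S.mean(axis=0)
    centered = S - row[None, :] - row[:, None] + S.mean()
    denom = (k - 1) * np.sum(centered**2)
    if denom == 0:  # no between-condition covariance structure at all
        eps = 1.0
    else:
        eps = float(np.trace(centered) ** 2 / denom)
    eps = min(max(eps, 1.0 / (k - 1)), 1.0)

    df1 = eps * (k - 1)
    df2 = eps * (k - 1) * (n - 1)
    p = float(stats.f.sf(F, df1, df2))
    eta = float(ss_cond / (ss_cond + ss_err)) if (ss_cond + ss_err) > 0 else 0.0
    return RmAnovaResult(F=F, df1=df1, df2=df2, epsilon_gg=eps, p=p, eta_sq=eta)


def bonferroni_contrasts(data: pd.DataFrame, compute_bf: bool = False) -> pd.DataFrame:
    """All pairwise paired contrasts between columns, Bonferroni-corrected.

    ``data`` is subjects x conditions (column names label the conditions,
    e.g. age bins). Returns one row per unordered pair: mean difference,
    t, Bonferroni-corrected p (multiplied by the number of contrasts,
    capped at 1) and a plain (unadjusted) 95% CI of the mean difference.
    """
    cols = list(data.columns)
    if len(cols) < 2:
        raise ValueError("need at least 2 conditions")
    pairs = list(combinations(cols, 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        res = paired_t(data[a].to_numpy(), data[b].to_numpy(), compute_bf=compute_bf)
        rows.append(
            {
                "comparison": f"{a} vs {b}",
                "mean_difference": float(np.mean(data[a].to_numpy() - data[b].to_numpy())),
                "t": res.t,
                "p_uncorrected": res.p,
                "p_bonferroni": min(res.p * m, 1.0),
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
            }
        )
    return pd.DataFrame(rows)
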