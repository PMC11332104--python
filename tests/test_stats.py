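"""Paired t, JZS Bayes factor, GG repeated-measures ANOVA, contrasts.

The Bayes factor is cross-checked against an independently written
g-prior quadrature (the inverse-gamma mixture representation of the
Cauchy prior), and the RM-ANOVA against a brute-force sums-of-squares
oracle and pingouin.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats as sps

from gazebench.stats import (
    DegenerateDataError,
    bonferroni_contrasts,
    jzs_bf10,
    paired_t,
    rm_anova_gg,
)


# --- paired t --------------------------------------------------------------


def test_paired_t_hand_computed_example():
    """Differences (1, 2, 3): mean 2, SD 1 -> t = 2*sqrt(3), df = 2."""
    res = paired_t(np.array([2.0, 4.0, 6.0]), np.array([1.0, 2.0, 3.0]), compute_bf=False)
    assert res.t == pytest.approx(2 * np.sqrt(3), abs=1e-12)
    assert res.df == 2
    assert res.cohens_d == pytest.approx(res.t / np.sqrt(3), abs=1e-12)


def test_zero_mean_difference_gives_t_zero_p_one():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    y = np.array([2.0, 1.0, 4.0, 3.0])
    res = paired_t(x, y, compute_bf=False)
    assert res.t == 0.0 and res.p == pytest.approx(1.0)


def test_ci_covers_mean_difference_and_matches_t_quantile():
    rng = np.random.default_rng(0)
    x = rng.normal(0.5, 1, 30)
    y = rng.normal(0.0, 1, 30)
    res = paired_t(x, y, compute_bf=False)
    d = x - y
    half = sps.t.ppf(0.975, 29) * d.std(ddof=1) / np.sqrt(30)
    assert res.ci_low == pytest.approx(d.mean() - half)
    assert res.ci_high == pytest.approx(d.mean() + half)


def test_identical_differences_are_degenerate():
    with pytest.raises(DegenerateDataError):
        paired_t(np.array([1.0, 2.0, 3.0]), np.array([0.0, 1.0, 2.0]))


def test_paired_t_type_one_error_calibrated():
    """Under the null, p < 0.05 in ~5% of replicates (binomial 99% CI)."""
    rng = np.random.default_rng(77)
    reps, n = 2000, 12
    x = rng.normal(size=(reps, n))
    y = rng.normal(size=(reps, n))
    d = x - y
    t = d.mean(axis=1) / (d.std(axis=1, ddof=1) / np.sqrt(n))
    p = 2 * sps.t.sf(np.abs(t), n - 1)
    rate = float((p < 0.05).mean())
    half = 2.576 * np.sqrt(0.05 * 0.95 / reps)
    assert abs(rate - 0.05) < half


# --- JZS Bayes factor ------------------------------------------------------


def bf10_g_quadrature(t, n, r=np.sqrt(2) / 2):
    """Independent oracle: inverse-gamma mixture form of the JZS prior."""
    nu = n - 1

    def numerator(g):
        # inverse-gamma(1/2, r^2/2) density
        dens = (r**2 / 2) ** 0.5 / np.sqrt(np.pi) * g ** (-1.5) * np.exp(-(r**2) / (2 * g))
        marg = (1 + n * g) ** -0.5 * (1 + t**2 / ((1 + n * g) * nu)) ** (-(nu + 1) / 2)
        return marg * dens

    num, _ = integrate.quad(numerator, 0, np.inf, limit=200)
    den = (1 + t**2 / nu) ** (-(nu + 1) / 2)
    return num / den


def test_no_effect_favours_the_null():
    assert jzs_bf10(0.0, 20) < 1.0


def test_bf10_increases_with_evidence():
    vals = [jzs_bf10(t, 15) for t in (0.0, 1.0, 2.0, 3.0, 5.0)]
    assert vals == sorted(vals)


@pytest.mark.parametrize("t", [0.5, 1.5, 2.5, 4.779])
@pytest.mark.parametrize("n", [5, 21, 60])
def test_bf10_agrees_with_g_prior_oracle(t, n):
    mine = jzs_bf10(t, n)
    oracle = bf10_g_quadrature(t, n)
    assert mine == pytest.approx(oracle, rel=1e-3)


def test_bf10_input_validation():
    with pytest.raises(ValueError):
        jzs_bf10(1.0, 1)
    with pytest.raises(ValueError):
        jzs_bf10(1.0, 10, r=0.0)


# --- RM-ANOVA --------------------------------------------------------------


def rm_anova_brute_force(a):
    """Direct sums-of-squares oracle via explicit loops."""
    n, k = a.shape
    grand = a.mean()
    ss_cond = sum(n * (a[:, j].mean() - grand) ** 2 for j in range(k))
    ss_subj = sum(k * (a[i, :].mean() - grand) ** 2 for i in range(n))
    ss_tot = sum((a[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_err = ss_tot - ss_cond - ss_subj
    F = (ss_cond / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))
    return F, ss_cond / (ss_cond + ss_err)


def test_rm_anova_matches_sums_of_squares_oracle():
    rng = np.random.default_rng(3)
    a = rng.normal(size=(4, 3))
    res = rm_anova_gg(a)
    F, eta = rm_anova_brute_force(a)
    assert res.F == pytest.approx(F, abs=1e-10)
    assert res.eta_sq == pytest.approx(eta, abs=1e-10)


def test_rm_anova_identical_columns_give_f_zero():
    base = np.arange(5.0)
    a = np.column_stack([base, base, base])
    res = rm_anova_gg(a)
    assert res.F == 0.0


def test_gg_epsilon_identities_hold_exactly():
    rng = np.random.default_rng(4)
    a = rng.normal(size=(21, 9))
    res = rm_anova_gg(a)
    k, n = 9, 21
    assert res.df1 == pytest.approx(res.epsilon_gg * (k - 1), abs=1e-12)
    assert res.df2 == pytest.approx(res.epsilon_gg * (k - 1) * (n - 1), abs=1e-12)
    assert 1.0 / (k - 1) <= res.epsilon_gg <= 1.0


def test_spherical_data_has_epsilon_near_one():
    rng = np.random.default_rng(5)
    eps = [rm_anova_gg(rng.normal(size=(30, 4))).epsilon_gg for _ in range(40)]
    assert np.median(eps) > 0.8


def test_rm_anova_agrees_with_pingouin():
    pingouin = pytest.importorskip("pingouin")
    rng = np.random.default_rng(6)
    a = rng.normal(size=(12, 5)) + rng.normal(size=(12, 1))
    long = pd.DataFrame(
        {
            "score": a.ravel(),
            "subject": np.repeat(np.arange(12), 5),
            "cond": np.tile(np.arange(5), 12),
        }
    )
    pg = pingouin.rm_anova(
        data=long, dv="score", within="cond", subject="subject", correction=True, detailed=True
    )
    res = rm_anova_gg(a)
    assert res.F == pytest.approx(float(pg.loc[0, "F"]), rel=1e-9)
    assert res.epsilon_gg == pytest.approx(float(pg.loc[0, "eps"]), rel=1e-6)
    p_gg = pg.loc[0, "p_GG_corr"] if "p_GG_corr" in pg.columns else pg.loc[0, "p-GG-corr"]
    assert res.p == pytest.approx(float(p_gg), rel=1e-6)


def test_constant_matrix_is_degenerate():
    with pytest.raises(DegenerateDataError):
        rm_anova_gg(np.ones((4, 3)))


# --- contrasts -------------------------------------------------------------


def test_nine_bins_give_thirty_six_contrasts():
    rng = np.random.default_rng(7)
    data = pd.DataFrame(rng.normal(size=(21, 9)), columns=[f"b{i}" for i in range(9)])
    out = bonferroni_contrasts(data)
    assert len(out) == 36
    assert (out["p_bonferroni"] >= out["p_uncorrected"] - 1e-15).all()
    assert (out["p_bonferroni"] <= 1.0).all()


def test_contrast_of_equal_mean_bins_has_zero_difference():
    a = np.array([1.0, 2.0, 3.0, 4.0])
    data = pd.DataFrame({"x": a, "y": a[::-1]})
    out = bonferroni_contrasts(data)
    assert out.loc[0, "mean_difference"] == pytest.approx(0.0)
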