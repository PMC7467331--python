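"""Targeted hypothesis tests and comparative models.

The replicative null — germline mutations track cell divisions at a fixed
per-division rate — makes quantitative predictions once the division schedule
of each sex is counted: the male bias alpha should scale like the ratio of
male-to-female division counts, the paternal age effect like the
spermatogonial stem cell (SSC) cycling rate, and intercepts like ages at
puberty.  This module books the division counts, derives the null constants,
and tests them against identity-link Poisson fits by constrained maximum
likelihood (LR tests).  It also provides the exact/chi-square 2x2 tests used
throughout, the cross-mammal regression of male bias on paternal age, and the
molecular-clock divergence-time grid T = K / mu_y over historical generation
times.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from ._datasets import CELL_DIVISION_STAGES, LIFE_HISTORY
from .rates_regression import RegressionFit, identity_poisson_loglik


# ---------------------------------------------------------------------------
# Cell-division bookkeeping
# ---------------------------------------------------------------------------


@dataclass
class CellDivisionModel:
    """Division counts of the germline by developmental stage for one species."""

    stage1: int  # zygote -> sex differentiation
    stage2_male: int  # -> birth, male germline
    stage2_female: int  # -> birth, female germline (oocytogenesis completes here)
    ssc_cycle_days: float
    puberty_age: float  # years
    reproduction_age: float  # years
    stage3_male: int = 0  # birth -> puberty, male
    spermatogenesis_tail: int = 4  # divisions completing spermatogenesis from an SSC

    def __post_init__(self) -> None:
        if self.reproduction_age < self.puberty_age:
            raise ValueError("reproduction age must not precede puberty")
        for count in (
            self.stage1,
            self.stage2_male,
            self.stage2_female,
            self.stage3_male,
            self.spermatogenesis_tail,
        ):
            if count < 0:
                raise ValueError("division counts must be nonnegative")


def species_model(species: str) -> CellDivisionModel:
    lh = LIFE_HISTORY[species]
    return CellDivisionModel(
        stage1=CELL_DIVISION_STAGES["stage1"],
        stage2_male=CELL_DIVISION_STAGES["stage2_male"],
        stage2_female=CELL_DIVISION_STAGES["stage2_female"],
        ssc_cycle_days=lh["ssc_cycle_days"],
        puberty_age=lh["puberty_m"],
        reproduction_age=lh["G_m"],
    )


def postpubertal_divisions(model: CellDivisionModel) -> int:
    """Male stage-4 divisions: (reproduction - puberty) * 365/cycle + tail."""
    return round(
        (model.reproduction_age - model.puberty_age) * 365.0 / model.ssc_cycle_days
        + model.spermatogenesis_tail
    )


def total_male_divisions(model: CellDivisionModel) -> int:
    return (
        model.stage1
        + model.stage2_male
        + model.stage3_male
        + postpubertal_divisions(model)
    )


def total_female_divisions(model: CellDivisionModel) -> int:
    return model.stage1 + model.stage2_female


def replicative_null_alpha(
    model_a: CellDivisionModel, model_b: CellDivisionModel
) -> float:
    """Expected fold-difference in alpha between two species if mutations are
    proportional to cell divisions: the ratio of male/female division-count
    ratios."""
    ratio_a = total_male_divisions(model_a) / total_female_divisions(model_a)
    ratio_b = total_male_divisions(model_b) / total_female_divisions(model_b)
    return ratio_a / ratio_b


# ---------------------------------------------------------------------------
# Constrained-likelihood (LR) tests of the Poisson age models
# ---------------------------------------------------------------------------


@dataclass
class LRTestResult:
    stat: float
    df: int
    p: float
    loglik_free: float
    loglik_constrained: float
    params_constrained: np.ndarray
    on_boundary: bool = False


def _maximize(negloglik, starts, bounds=None) -> tuple[np.ndarray, float]:
    """Multi-start numeric maximization; the best-likelihood result is kept."""
    best = None
    for x0 in starts:
        res = optimize.minimize(
            negloglik, np.asarray(x0, dtype=float), method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-11, "maxiter": 5000},
        )
        if best is None or res.fun < best.fun:
            best = res
    return np.asarray(best.x), -float(best.fun)


def _lr_result(
    ll_free: float, ll_con: float, params_con: np.ndarray, df: int
) -> LRTestResult:
    stat = max(0.0, 2.0 * (ll_free - ll_con))
    return LRTestResult(
        stat=stat,
        df=df,
        p=float(stats.chi2.sf(stat, df)),
        loglik_free=ll_free,
        loglik_constrained=ll_con,
        params_constrained=params_con,
    )


def lr_test_slope(
    counts, ages_at_birth, gestation: float, beta1_null: float, fit: RegressionFit
) -> LRTestResult:
    """LR test of a fixed age-effect slope against the free 2-parameter fit.

    Used for replicative nulls on the paternal slope, e.g. a slope scaled up
    by the ratio of SSC cycling rates, or equality with an external estimate.
    """
    ages = np.asarray(ages_at_birth, dtype=float) - gestation
    counts = np.asarray(counts, dtype=float)

    def negloglik(params):
        return -identity_poisson_loglik((params[0], beta1_null), counts, ages)

    starts = [[max(counts.mean() - beta1_null * ages.mean(), 0.5)], [1.0], [10.0]]
    params, ll_con = _maximize(negloglik, starts)
    result = _lr_result(fit.loglik, ll_con, np.append(params, beta1_null), df=1)
    if params[0] <= 0:
        result.on_boundary = True
    return result


def lr_test_alpha_ratio(
    counts_m,
    ages_m,
    counts_f,
    ages_f,
    gestation: float,
    G_m: float,
    G_f: float,
    alpha_null: float,
    fit_m: RegressionFit,
    fit_f: RegressionFit,
) -> LRTestResult:
    """LR test fixing alpha = (male mean at G_m)/(female mean at G_f).

    Under the constraint the male intercept is eliminated:
    b0_m = alpha*(b0_f + b1_f*G_f) - b1_m*G_m; the remaining three parameters
    (b1_m, b0_f, b1_f) are profiled numerically.
    """
    am = np.asarray(ages_m, dtype=float) - gestation
    af = np.asarray(ages_f, dtype=float) - gestation
    cm = np.asarray(counts_m, dtype=float)
    cf = np.asarray(counts_f, dtype=float)

    def negloglik(params):
        b1m, b0f, b1f = params
        b0m = alpha_null * (b0f + b1f * G_f) - b1m * G_m
        return -(
            identity_poisson_loglik((b0m, b1m), cm, am)
            + identity_poisson_loglik((b0f, b1f), cf, af)
        )

    starts = [
        [fit_m.beta1, fit_f.beta0, fit_f.beta1],
        [0.5, max(cf.mean(), 1.0), 0.0],
        [1.5, 1.0, 0.5],
    ]
    params, ll_con = _maximize(negloglik, starts)
    ll_free = fit_m.loglik + fit_f.loglik
    return _lr_result(ll_free, ll_con, params, df=1)


def lr_test_mean_ratio(
    counts_a,
    ages_a,
    counts_b,
    ages_b,
    gestation_a: float,
    gestation_b: float,
    G_a: float,
    G_b: float,
    ratio_null: float,
    fit_a: RegressionFit,
    fit_b: RegressionFit,
) -> LRTestResult:
    """LR test fixing the ratio of fitted means of two datasets at reference
    ages: mean_a(G_a) = ratio_null * mean_b(G_b).

    Covers the maternal-age null (human/baboon maternal counts in the ratio
    of their reproductive ages) and the puberty-intercept null (with ages
    measured from puberty and G = 0).  The constraint eliminates dataset A's
    intercept; the other three parameters are profiled.
    """
    aa = np.asarray(ages_a, dtype=float) - gestation_a
    ab = np.asarray(ages_b, dtype=float) - gestation_b
    ca = np.asarray(counts_a, dtype=float)
    cb = np.asarray(counts_b, dtype=float)

    def negloglik(params):
        b1a, b0b, b1b = params
        b0a = ratio_null * (b0b + b1b * G_b) - b1a * G_a
        return -(
            identity_poisson_loglik((b0a, b1a), ca, aa)
            + identity_poisson_loglik((b0b, b1b), cb, ab)
        )

    starts = [
        [fit_a.beta1, fit_b.beta0, fit_b.beta1],
        [0.0, max(cb.mean(), 1.0), 0.0],
        [1.0, 1.0, 0.5],
    ]
    params, ll_con = _maximize(negloglik, starts)
    ll_free = fit_a.loglik + fit_b.loglik
    return _lr_result(ll_free, ll_con, params, df=1)


def lr_test_slopes_equal(
    counts_a, ages_a, counts_b, ages_b, gestation_a: float, gestation_b: float,
    fit_a: RegressionFit, fit_b: RegressionFit,
) -> LRTestResult:
    """LR test of a shared age-effect slope across two datasets (3- vs
    4-parameter model), e.g. the species-equality test per sex."""
    aa = np.asarray(ages_a, dtype=float) - gestation_a
    ab = np.asarray(ages_b, dtype=float) - gestation_b
    ca = np.asarray(counts_a, dtype=float)
    cb = np.asarray(counts_b, dtype=float)

    def negloglik(params):
        b0a, b0b, b1 = params
        return -(
            identity_poisson_loglik((b0a, b1), ca, aa)
            + identity_poisson_loglik((b0b, b1), cb, ab)
        )

    starts = [
        [fit_a.beta0, fit_b.beta0, (fit_a.beta1 + fit_b.beta1) / 2],
        [max(ca.mean(), 1.0), max(cb.mean(), 1.0), 0.0],
    ]
    params, ll_con = _maximize(negloglik, starts)
    ll_free = fit_a.loglik + fit_b.loglik
    return _lr_result(ll_free, ll_con, params, df=1)


# ---------------------------------------------------------------------------
# 2x2 tests
# ---------------------------------------------------------------------------


def fisher_exact_2x2(table) -> float:
    """Two-tailed Fisher exact p: the sum of hypergeometric probabilities of
    tables (with the observed margins) no more probable than the observed one."""
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("need a nonnegative 2x2 table")
    if table.sum() == 0:
        raise ValueError("zero total")
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def chi2_alpha_between_species(
    counts_a: tuple[int, int], counts_b: tuple[int, int], correction: bool = True
) -> float:
    """Pearson chi-square p for equality of paternal/maternal phased-count
    proportions between two species.  Yates continuity correction on by
    default (the convention of R's chisq.test for 2x2 tables)."""
    table = np.asarray([counts_a, counts_b], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero margin in the 2x2 table")
    _, p, _, _ = stats.chi2_contingency(table, correction=correction)
    return float(p)


# ---------------------------------------------------------------------------
# Cross-mammal male-bias regression
# ---------------------------------------------------------------------------


def alpha_vs_paternal_age_regression(
    alphas, mean_paternal_ages, scale: str = "fraction"
) -> dict:
    """Ordinary least squares of the male mutation bias on mean paternal age
    across species.

    The default regresses the paternal fraction alpha/(1+alpha) — the scale on
    which the bias is bounded and cross-study estimates are comparable — on
    age; ``scale='alpha'`` uses the raw ratio instead.
    """
    alphas = np.asarray(alphas, dtype=float)
    ages = np.asarray(mean_paternal_ages, dtype=float)
    if alphas.size < 3:
        raise ValueError("need at least 3 species points")
    y = alphas / (1 + alphas) if scale == "fraction" else alphas
    res = sm.OLS(y, sm.add_constant(ages)).fit()
    lo, hi = res.conf_int()[1]
    return {
        "slope": float(res.params[1]),
        "intercept": float(res.params[0]),
        "ci": (float(lo), float(hi)),
        "p": float(res.pvalues[1]),
        "scale": scale,
    }


# ---------------------------------------------------------------------------
# Divergence-time grid
# ---------------------------------------------------------------------------


@dataclass
class DivergenceGrid:
    """Inputs of the molecular-clock grid T = K / mu_y.

    K is the lineage neutral substitution rate per bp; beta are the
    identity-link Poisson parameters per sex; paternal generation times G_m
    span [g_min, g_max]; the paternal/maternal generation-time ratio spans
    ratio_range (maternal age G_f = G_m / ratio).
    """

    K: float
    beta_male: tuple[float, float]
    beta_female: tuple[float, float]
    H: float
    g_m_range: tuple[float, float]
    ratio_range: tuple[float, float] = (0.8, 1.2)
    n_g: int = 30
    n_ratio: int = 9


def divergence_time_grid(grid: DivergenceGrid) -> pd.DataFrame:
    """Mean time to the common ancestor, T = K / mu_y, over the grid of
    paternal generation times and paternal-to-maternal generation-time ratios.

    Returns a long table with columns G_m, ratio, G_f, mu_y, T_years.  Grid
    points with non-positive mu_y are rejected.
    """
    g_values = np.linspace(*grid.g_m_range, grid.n_g)
    ratios = np.linspace(*grid.ratio_range, grid.n_ratio)
    b0m, b1m = grid.beta_male
    b0f, b1f = grid.beta_female
    rows = []
    for g_m, ratio in itertools.product(g_values, ratios):
        g_f = g_m / ratio
        mu_m = (b0m + b1m * g_m) / (2 * grid.H)
        mu_f = (b0f + b1f * g_f) / (2 * grid.H)
        mu_y = 2 * (mu_m + mu_f) / (g_m + g_f)
        if mu_y <= 0:
            raise ValueError(f"non-positive yearly rate at G_m={g_m}, ratio={ratio}")
        rows.append(
            {"G_m": g_m, "ratio": ratio, "G_f": g_f, "mu_y": mu_y, "T_years": grid.K / mu_y}
        )
    return pd.DataFrame(rows)
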