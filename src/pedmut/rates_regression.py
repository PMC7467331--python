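"""Sex-specific mutation counts, identity-link Poisson age models, and rates.

The chain implemented here converts filtered, phased, error-rated DNM calls
into the study's quantitative results:

* adjusted counts:  the error- and genome-scaled integer count of DNMs
  attributed to one parental sex in one trio,

      upsilon = int[ a * (y1*(1-FDR1) + y2*(1-FDR2)) / ((1-FNR) * (O/H)) ]

  where a is the sex's phased fraction, y1/y2 the singlet/doublet calls,
  O the surveyed (orthologous accessible) territory and H the haploid
  autosomal genome size the counts are scaled up to;
* Poisson regression with identity link: counts ~ Poisson(b0 + b1 * A) with
  A the parental age at conception (age at birth minus gestation), fitted
  separately per sex and species — the age effect is additive, not
  multiplicative, so the default log link would misspecify the model;
* per-generation and per-year rates at typical conception ages G:
  mu_g^s(G) = (b0 + b1*G) / (2H),  mu_g = mu_g^m + mu_g^f,
  mu_y = 2*(mu_g^m + mu_g^f) / (G_m + G_f),
  with confidence intervals from parametric draws of the coefficients;
* the male-to-female mutation ratio alpha, either as the ratio of phased
  transmitted counts (with a genetic-map block bootstrap CI) or as the ratio
  of fitted means at typical ages;
* mutation rates by genomic compartment with exact Poisson rate-ratio tests;
* an AIC comparison of linear vs exponential maternal age models.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import gammaln

from .io_formats import GeneticMap


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class AdjustedCount:
    trio_id: str
    sex: str
    upsilon: int
    components: dict


def adjust_counts(
    y1: int,
    y2: int,
    fdr1: float,
    fdr2: float,
    fnr: float,
    a_s: float,
    O: float,
    H: float,
    trio_id: str = "",
    sex: str = "",
) -> AdjustedCount:
    """Error-adjusted, genome-scaled DNM count for one trio and one sex.

    False-positive contamination shrinks the counts ((1-FDR) factors); the
    result is scaled up for missed true DNMs (divide by 1-FNR) and from the
    surveyed territory O to the haploid genome H (divide by O/H).  "int" is
    round-half-away-from-zero.  Degenerate error rates (FDR or FNR = 1) yield
    zero with a warning.
    """
    if not 0 <= a_s <= 1:
        raise ValueError("phased fraction must lie in [0, 1]")
    if fdr1 >= 1 or fdr2 >= 1 or fnr >= 1:
        warnings.warn("FDR or FNR = 1; adjusted count set to 0", stacklevel=2)
        upsilon = 0
    else:
        raw = a_s * (y1 * (1 - fdr1) + y2 * (1 - fdr2)) / ((1 - fnr) * (O / H))
        upsilon = _round_half_away(raw)
    return AdjustedCount(
        trio_id=trio_id,
        sex=sex,
        upsilon=upsilon,
        components=dict(
            y1=y1, y2=y2, fdr1=fdr1, fdr2=fdr2, fnr=fnr, a_s=a_s, O=O, H=H
        ),
    )


@dataclass
class RegressionFit:
    """Identity-link Poisson fit of DNM counts on parental age at conception."""

    sex: str
    species: str
    beta0: float
    beta1: float
    cov: np.ndarray  # 2x2 covariance of (beta0, beta1)
    loglik: float
    gestation: float
    n: int

    def mean_at(self, age_at_conception) -> np.ndarray:
        return self.beta0 + self.beta1 * np.asarray(age_at_conception, dtype=float)

    def wald_ci(self, which: int, level: float = 0.95) -> tuple[float, float]:
        z = stats.norm.ppf(0.5 + level / 2)
        est = (self.beta0, self.beta1)[which]
        se = math.sqrt(self.cov[which, which])
        return est - z * se, est + z * se

    def slope_p(self) -> float:
        z = self.beta1 / math.sqrt(self.cov[1, 1])
        return 2 * stats.norm.sf(abs(z))

    def draw_coefficients(self, n_draws: int, rng: np.random.Generator) -> np.ndarray:
        """Parametric draws of (beta0, beta1) from the fit's normal approximation."""
        return rng.multivariate_normal([self.beta0, self.beta1], self.cov, size=n_draws)


def identity_poisson_loglik(params, counts, ages) -> float:
    """Written-out log-likelihood of the identity-link Poisson model."""
    b0, b1 = params
    mu = b0 + b1 * np.asarray(ages, dtype=float)
    if np.any(mu <= 0):
        return -np.inf
    counts = np.asarray(counts, dtype=float)
    return float(np.sum(counts * np.log(mu) - mu - gammaln(counts + 1)))


def fit_age_model(
    counts,
    ages_at_birth,
    gestation: float,
    sex: str = "",
    species: str = "",
    dispersion: str | None = "pearson",
) -> RegressionFit:
    """Maximum-likelihood identity-link Poisson fit of counts on age at conception.

    Trios with a missing parental age must be excluded by the caller.  The fit
    is refused (with diagnostics) when fewer than 3 trios remain, on
    non-convergence, or when the fitted mean is non-positive over the observed
    age range.

    Point estimates and the log-likelihood are always the Poisson ML values.
    With ``dispersion="pearson"`` (the default) the coefficient covariance is
    scaled by the Pearson dispersion estimate, floored at 1: error-adjusted
    DNM counts carry extra noise beyond Poisson sampling (estimated FDR/FNR
    and phased fractions enter multiplicatively), and the quasi-likelihood
    scale lets the Wald intervals reflect it.  ``dispersion=None`` keeps the
    pure ML covariance.
    """
    counts = np.asarray(counts, dtype=float)
    ages = np.asarray(ages_at_birth, dtype=float) - gestation
    if counts.shape != ages.shape:
        raise ValueError("counts and ages must align")
    if np.any(np.isnan(ages)) or np.any(np.isnan(counts)):
        raise ValueError("missing ages/counts must be excluded before fitting")
    if counts.size < 3:
        raise ValueError("need at least 3 trios with the relevant parental age")

    exog = sm.add_constant(ages)
    start = np.polyfit(ages, counts, 1)[::-1]  # OLS start (intercept, slope)
    if start[0] + start[1] * ages.min() <= 0 or start[0] + start[1] * ages.max() <= 0:
        start = np.array([max(counts.mean(), 0.5), 0.0])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.GLM(
                counts,
                exog,
                family=sm.families.Poisson(link=sm.families.links.Identity()),
            )
            res = model.fit(start_params=start, maxiter=200)
        beta = np.asarray(res.params, dtype=float)
        cov = np.asarray(res.cov_params(), dtype=float)
        if dispersion == "pearson" and counts.size > 2:
            scale = float(res.pearson_chi2) / (counts.size - 2)
            cov = cov * max(1.0, scale)
        llf = float(res.llf)
        converged = bool(res.converged)
    except (ValueError, np.linalg.LinAlgError) as exc:
        raise RuntimeError(f"identity-link Poisson fit failed: {exc}") from exc
    if not converged:
        raise RuntimeError("identity-link Poisson fit did not converge")
    fitted = beta[0] + beta[1] * ages
    if np.any(fitted <= 0):
        raise RuntimeError(
            "fitted mean non-positive over the observed age range: "
            f"beta={beta}, age range=({ages.min()}, {ages.max()})"
        )
    return RegressionFit(
        sex=sex,
        species=species,
        beta0=float(beta[0]),
        beta1=float(beta[1]),
        cov=cov,
        loglik=llf,
        gestation=gestation,
        n=counts.size,
    )


@dataclass
class RateEstimate:
    value: float
    ci: tuple[float, float]
    draws: np.ndarray | None = None


def _percentile_ci(draws: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    alpha = (1 - level) / 2
    lo, hi = np.nanpercentile(draws, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)


def per_generation_rate(
    fit_male: RegressionFit,
    fit_female: RegressionFit,
    G_m: float,
    G_f: float,
    H: float,
    n_draws: int = 1000,
    rng: np.random.Generator | None = None,
) -> dict[str, RateEstimate]:
    """Per-bp per-generation mutation rate at typical conception ages (G_m, G_f).

    mu_g^s = (b0^s + b1^s G^s) / (2H) per sex; the sex-averaged per-generation
    rate is their sum.  CIs come from ``n_draws`` parametric draws of the
    regression coefficients.
    """
    rng = np.random.default_rng() if rng is None else rng
    out: dict[str, RateEstimate] = {}
    per_sex_draws = {}
    for key, fit, G in (("male", fit_male, G_m), ("female", fit_female, G_f)):
        point = float(fit.mean_at(G)) / (2 * H)
        draws = fit.draw_coefficients(n_draws, rng)
        mu_draws = (draws[:, 0] + draws[:, 1] * G) / (2 * H)
        out[key] = RateEstimate(point, _percentile_ci(mu_draws), mu_draws)
        per_sex_draws[key] = mu_draws
    total_draws = per_sex_draws["male"] + per_sex_draws["female"]
    out["total"] = RateEstimate(
        out["male"].value + out["female"].value,
        _percentile_ci(total_draws),
        total_draws,
    )
    return out


def yearly_rate(
    per_gen: dict[str, RateEstimate], G_m: float, G_f: float
) -> RateEstimate:
    """Sex-averaged per-bp yearly rate: mu_y = 2 (mu_g^m + mu_g^f) / (G_m + G_f)."""
    denom = G_m + G_f
    value = 2 * (per_gen["male"].value + per_gen["female"].value) / denom
    draws = None
    ci = (value, value)
    if per_gen["male"].draws is not None and per_gen["female"].draws is not None:
        draws = 2 * (per_gen["male"].draws + per_gen["female"].draws) / denom
        ci = _percentile_ci(draws)
    return RateEstimate(value, ci, draws)


# ---------------------------------------------------------------------------
# Block bootstrap
# ---------------------------------------------------------------------------


def _assign_blocks(
    records: pd.DataFrame, genetic_map: GeneticMap, block_cm: float
) -> tuple[np.ndarray, int]:
    """Map each record to the index of its 50 cM (by default) genome block.

    The genome is partitioned into contiguous blocks chromosome by chromosome
    using the genetic map; the final partial block of each chromosome is kept
    as its own block.  Returns per-record block indices and the total number
    of blocks in the partition (empty blocks included).
    """
    block_index = np.full(len(records), -1, dtype=int)
    offset = 0
    for chrom in genetic_map.chromosomes:
        pos0, cm0 = genetic_map.chrom_maps[chrom][0][0], genetic_map.chrom_maps[chrom][1][0]
        length_cm = genetic_map.chrom_length_cm(chrom)
        n_blocks = max(1, int(np.ceil(length_cm / block_cm)))
        mask = (records["chrom"] == chrom).to_numpy()
        if mask.any():
            cm = genetic_map.cm_at(chrom, records.loc[mask, "pos"].to_numpy()) - cm0
            idx = np.clip((cm / block_cm).astype(int), 0, n_blocks - 1)
            block_index[mask] = offset + idx
        offset += n_blocks
    if (block_index < 0).any():
        missing = records.loc[block_index < 0, "chrom"].unique()
        raise ValueError(f"records on chromosomes absent from the map: {list(missing)}")
    return block_index, offset


def block_bootstrap(
    records: pd.DataFrame,
    genetic_map: GeneticMap,
    statistic,
    block_cm: float = 50.0,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
    level: float = 0.95,
) -> tuple[tuple[float, float], np.ndarray]:
    """Percentile CI of a statistic under bootstrap resampling of genome blocks.

    ``statistic`` must be a pure function of a record multiset (a DataFrame
    slice).  Blocks of ``block_cm`` genetic length are resampled with
    replacement ``n_boot`` times.  Refuses to run with fewer than 2 non-empty
    blocks.
    """
    rng = np.random.default_rng() if rng is None else rng
    block_index, n_blocks = _assign_blocks(records, genetic_map, block_cm)
    if len(np.unique(block_index)) < 2:
        raise ValueError("need at least 2 non-empty blocks for a block bootstrap")
    groups = {b: records.iloc[np.flatnonzero(block_index == b)] for b in range(n_blocks)}
    values = np.empty(n_boot)
    for b in range(n_boot):
        chosen = rng.integers(0, n_blocks, size=n_blocks)
        sample = pd.concat([groups[c] for c in chosen], axis=0)
        values[b] = statistic(sample)
    return _percentile_ci(values, level), values


def alpha_from_counts(n_paternal: int, n_maternal: int) -> float:
    """Point estimate of the male-to-female mutation ratio from phased counts."""
    if n_paternal < 0 or n_maternal < 0:
        raise ValueError("counts must be nonnegative")
    if n_maternal == 0:
        warnings.warn("zero maternal count; alpha is infinite", stacklevel=2)
        return math.inf
    return n_paternal / n_maternal


def alpha_from_phased(
    phased: pd.DataFrame,
    genetic_map: GeneticMap,
    block_cm: float = 50.0,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
) -> dict:
    """Alpha with a block-bootstrap CI from a table of phased DNMs.

    ``phased`` needs columns chrom, pos, consensus (paternal/maternal).  The
    bootstrap resamples genome blocks with replacement and recomputes the
    paternal/maternal ratio; per-block counts are precomputed so the resampling
    is a vectorized sum.
    """
    rng = np.random.default_rng() if rng is None else rng
    phased = phased[phased["consensus"].isin(["paternal", "maternal"])]
    if phased.empty:
        raise ValueError("no phased DNMs")
    block_index, n_blocks = _assign_blocks(phased, genetic_map, block_cm)
    is_pat = (phased["consensus"] == "paternal").to_numpy()
    pat_per_block = np.bincount(block_index, weights=is_pat, minlength=n_blocks)
    mat_per_block = np.bincount(block_index, weights=~is_pat, minlength=n_blocks)
    if len(np.unique(block_index)) < 2:
        raise ValueError("need at least 2 non-empty blocks for a block bootstrap")
    chosen = rng.integers(0, n_blocks, size=(n_boot, n_blocks))
    pat = pat_per_block[chosen].sum(axis=1)
    mat = mat_per_block[chosen].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(mat > 0, pat / np.maximum(mat, 1), np.inf)
        fractions = pat / (pat + mat)
    n_pat, n_mat = int(is_pat.sum()), int((~is_pat).sum())
    finite = ratios[np.isfinite(ratios)]
    return {
        "n_paternal": n_pat,
        "n_maternal": n_mat,
        "alpha": alpha_from_counts(n_pat, n_mat),
        "fraction_paternal": n_pat / (n_pat + n_mat),
        "alpha_ci": _percentile_ci(finite) if finite.size else (math.inf, math.inf),
        "fraction_ci": _percentile_ci(fractions),
    }


def alpha_fitted(
    fit_male: RegressionFit,
    fit_female: RegressionFit,
    G_m: float,
    G_f: float,
    n_draws: int = 1000,
    rng: np.random.Generator | None = None,
) -> dict:
    """Alpha as the ratio of fitted mean counts at typical conception ages."""
    rng = np.random.default_rng() if rng is None else rng
    num = float(fit_male.mean_at(G_m))
    den = float(fit_female.mean_at(G_f))
    if den <= 0:
        raise ValueError("female fitted mean non-positive at G_f")
    draws_m = fit_male.draw_coefficients(n_draws, rng)
    draws_f = fit_female.draw_coefficients(n_draws, rng)
    mu_m = draws_m[:, 0] + draws_m[:, 1] * G_m
    mu_f = draws_f[:, 0] + draws_f[:, 1] * G_f
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = mu_m / mu_f
    ratio = ratio[np.isfinite(ratio) & (mu_f > 0)]
    return {"alpha": num / den, "alpha_ci": _percentile_ci(ratio)}


# ---------------------------------------------------------------------------
# Compartment rates
# ---------------------------------------------------------------------------


def poisson_rate_ratio_test(
    n_a: int, n_b: int, size_a: float, size_b: float
) -> float:
    """Exact conditional test of equal Poisson rates in two compartments.

    Conditional on the total count, n_a ~ Binomial(n_a + n_b, N_a/(N_a+N_b))
    under the null of equal rates; the two-sided p doubles the smaller tail.
    """
    total = n_a + n_b
    if total == 0:
        return 1.0
    p0 = size_a / (size_a + size_b)
    lower = stats.binom.cdf(n_a, total, p0)
    upper = stats.binom.sf(n_a - 1, total, p0)
    return float(min(1.0, 2 * min(lower, upper)))


def compartment_rates(
    counts: pd.DataFrame,
    sizes: pd.DataFrame,
    fdr_by_trio: dict[str, float],
    fnr_by_trio: dict[str, float],
) -> tuple[dict[str, float], dict[tuple[str, str], float]]:
    """Pooled per-generation rates per genome compartment and pairwise tests.

    ``counts`` columns: trio_id, compartment, count; ``sizes`` columns:
    trio_id, compartment, bp (haploid).  Each trio's contribution is weighted
    by (1 - FDR_i)/(1 - FNR_i); the denominator is the summed diploid
    compartment size.  Zero-size compartments are skipped.  The pairwise exact
    rate-ratio test uses the raw (unweighted) integer counts.
    """
    rates: dict[str, float] = {}
    raw: dict[str, int] = {}
    denoms: dict[str, float] = {}
    for comp, sub in counts.groupby("compartment"):
        weighted = 0.0
        for row in sub.itertuples(index=False):
            weighted += (
                row.count
                * (1 - fdr_by_trio[row.trio_id])
                / (1 - fnr_by_trio[row.trio_id])
            )
        size = sizes.loc[sizes["compartment"] == comp, "bp"].sum()
        if size == 0:
            continue
        denoms[comp] = 2.0 * float(size)
        rates[comp] = weighted / denoms[comp]
        raw[comp] = int(sub["count"].sum())
    tests: dict[tuple[str, str], float] = {}
    comps = sorted(rates)
    for i, a in enumerate(comps):
        for b in comps[i + 1 :]:
            tests[(a, b)] = poisson_rate_ratio_test(
                raw[a], raw[b], denoms[a], denoms[b]
            )
    return rates, tests


# ---------------------------------------------------------------------------
# Linear vs exponential maternal age model
# ---------------------------------------------------------------------------


def poisson_aic(counts, means, k: int) -> float:
    """AIC = 2k - 2 lnL under independent Poisson observations with given means."""
    counts = np.asarray(counts, dtype=float)
    means = np.asarray(means, dtype=float)
    if np.any(means <= 0):
        raise ValueError("nonpositive Poisson means")
    ll = float(np.sum(counts * np.log(means) - means - gammaln(counts + 1)))
    return 2 * k - 2 * ll


def exponential_maternal_aic(
    counts,
    ages_at_birth,
    gestation: float,
    linear_params: tuple[float, float],
    exponential_params: tuple[float, float],
    k_linear: int = 0,
    k_exponential: int = 0,
) -> float:
    """Delta AIC (exponential minus linear) of externally estimated maternal models.

    Linear mean: b0 + b1*A; exponential mean: c0*exp(c1*A), with A the age at
    conception.  Externally fixed parameters contribute k = 0 free parameters.
    Negative values favour the exponential model.
    """
    ages = np.asarray(ages_at_birth, dtype=float) - gestation
    b0, b1 = linear_params
    c0, c1 = exponential_params
    aic_lin = poisson_aic(counts, b0 + b1 * ages, k_linear)
    aic_exp = poisson_aic(counts, c0 * np.exp(c1 * ages), k_exponential)
    return aic_exp - aic_lin


def scale_external_params(value: float, H: float, R: float) -> float:
    """Rescale an externally published coefficient from a callable genome of
    R bp to this study's haploid genome of H bp."""
    if R <= 0:
        raise ValueError("R must be positive")
    return value * H / R
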