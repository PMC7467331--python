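"""Adjusted counts, identity-link Poisson fits, rates, alpha, bootstrap."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize
from scipy.special import gammaln

from pedmut import rates_regression as rr
from pedmut.io_formats import GeneticMap


class TestAdjustCounts:
    def test_hand_evaluated_formula(self):
        # a=0.8, y1=10 (FDR 0.2), y2=2 (FDR 0.5), FNR=0.1, O=H:
        # 0.8 * (8 + 1) / 0.9 = 8.0
        adj = rr.adjust_counts(10, 2, 0.2, 0.5, 0.1, 0.8, O=1.0, H=1.0)
        assert adj.upsilon == 8

    def test_zero_phased_fraction(self):
        assert rr.adjust_counts(10, 2, 0.2, 0.5, 0.1, 0.0, 1.0, 1.0).upsilon == 0

    def test_genome_scaling(self):
        # O = H: factor 1; halving O doubles the scaled count
        full = rr.adjust_counts(10, 0, 0.0, 0.0, 0.0, 1.0, O=100.0, H=100.0)
        half = rr.adjust_counts(10, 0, 0.0, 0.0, 0.0, 1.0, O=50.0, H=100.0)
        assert full.upsilon == 10
        assert half.upsilon == 20

    def test_degenerate_error_rates_warn(self):
        with pytest.warns(UserWarning):
            assert rr.adjust_counts(10, 0, 1.0, 0.0, 0.0, 1.0, 1.0, 1.0).upsilon == 0

    def test_rounding_half_away_from_zero(self):
        # 0.5 * 9 / 1 = 4.5 -> 5, not 4
        adj = rr.adjust_counts(9, 0, 0.0, 0.0, 0.0, 0.5, 1.0, 1.0)
        assert adj.upsilon == 5

    def test_homogeneity_up_to_rounding(self, rng):
        for _ in range(25):
            y1 = int(rng.integers(0, 120))
            y2 = int(rng.integers(0, 8))
            fdr1, fdr2, fnr = rng.uniform(0, 0.6, size=3)
            a = rng.uniform(0, 1)
            one = rr.adjust_counts(y1, y2, fdr1, fdr2, fnr, a, 1.0, 1.0).upsilon
            two = rr.adjust_counts(2 * y1, 2 * y2, fdr1, fdr2, fnr, a, 1.0, 1.0).upsilon
            assert abs(two - 2 * one) <= 1  # doubling up to integer rounding


def direct_ml_fit(counts, ages):
    """Independent maximization of the written-out Poisson log-likelihood."""

    def nll(params):
        b0, b1 = params
        mu = b0 + b1 * ages
        if np.any(mu <= 0):
            return 1e12
        return -np.sum(counts * np.log(mu) - mu - gammaln(counts + 1))

    best = None
    for x0 in ([counts.mean(), 0.0], [1.0, 1.0], [10.0, 0.5]):
        res = optimize.minimize(nll, x0, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12})
        if best is None or res.fun < best.fun:
            best = res
    return best.x, -best.fun


class TestFitAgeModel:
    def test_exact_linear_counts(self):
        # counts = age + 10 at ages 10, 20, 30: slope 1, intercept 10 + C
        C = 0.75
        fit = rr.fit_age_model([20, 30, 40], [10, 20, 30], gestation=C)
        assert fit.beta1 == pytest.approx(1.0, abs=1e-6)
        assert fit.beta0 == pytest.approx(10 + C, abs=1e-5)

    def test_matches_direct_loglik_maximization(self, rng):
        for _ in range(5):
            ages = rng.uniform(15, 45, size=12)
            counts = rng.poisson(5 + 1.2 * ages)
            fit = rr.fit_age_model(counts, ages, gestation=0.0)
            params, ll = direct_ml_fit(counts.astype(float), ages)
            assert fit.loglik == pytest.approx(ll, abs=1e-6)
            assert fit.beta0 == pytest.approx(params[0], abs=1e-3)
            assert fit.beta1 == pytest.approx(params[1], abs=1e-4)

    def test_constant_counts_slope_ci_covers_zero(self, rng):
        counts = rng.poisson(30, size=20)
        fit = rr.fit_age_model(counts, rng.uniform(20, 40, size=20), 0.0)
        lo, hi = fit.wald_ci(1)
        assert lo < 0 < hi

    def test_requires_three_trios(self):
        with pytest.raises(ValueError, match="3 trios"):
            rr.fit_age_model([5, 6], [20, 30], 0.0)

    def test_missing_ages_must_be_excluded(self):
        with pytest.raises(ValueError, match="missing"):
            rr.fit_age_model([5, 6, 7], [20.0, np.nan, 30.0], 0.0)


def _fit(beta0, beta1, var0=1e-12, var1=1e-12):
    return rr.RegressionFit(
        sex="male", species="s", beta0=beta0, beta1=beta1,
        cov=np.diag([var0, var1]), loglik=0.0, gestation=0.0, n=10,
    )


class TestRates:
    def test_unit_check_rate_equals_generation_time(self, rng):
        H = 1000.0
        fit = _fit(0.0, 2 * H)
        rates = rr.per_generation_rate(fit, _fit(0.0, 2 * H), 7.0, 3.0, H, rng=rng)
        assert rates["male"].value == pytest.approx(7.0)
        assert rates["female"].value == pytest.approx(3.0)

    def test_doubling_genome_halves_rate(self, rng):
        f = _fit(10.0, 1.0)
        a = rr.per_generation_rate(f, f, 30.0, 30.0, H=1e9, rng=rng)
        b = rr.per_generation_rate(f, f, 30.0, 30.0, H=2e9, rng=rng)
        assert a["total"].value == pytest.approx(2 * b["total"].value)

    def test_yearly_rate_reduces_to_ratio_at_equal_ages(self, rng):
        f = _fit(10.0, 1.0)
        per_gen = rr.per_generation_rate(f, f, 30.0, 30.0, H=1e9, rng=rng)
        yearly = rr.yearly_rate(per_gen, 30.0, 30.0)
        assert yearly.value == pytest.approx(per_gen["total"].value / 30.0)

    def test_ci_width_stable_across_seeds(self, rng):
        # two independent draw sets at 1,000 draws differ by < 2% in width
        fit_m = _fit(8.0, 1.35, var0=4.0, var1=0.01)
        fit_f = _fit(2.4, 0.37, var0=1.0, var1=0.004)
        widths = []
        for seed in (1, 2):
            r = rr.per_generation_rate(
                fit_m, fit_f, 32.0, 28.2, 2e7,
                n_draws=1000, rng=np.random.default_rng(seed),
            )
            lo, hi = r["total"].ci
            widths.append(hi - lo)
        assert abs(widths[0] - widths[1]) / widths[0] < 0.02


def uniform_map(total_cm=3500.0, chrom_bp=10_000_000):
    return GeneticMap(
        {
            "chr1": (np.array([1.0, chrom_bp]), np.array([0.0, total_cm / 2])),
            "chr2": (np.array([1.0, chrom_bp]), np.array([0.0, total_cm / 2])),
        }
    )


class TestAlpha:
    def test_counts_ratio(self):
        assert rr.alpha_from_counts(12, 3) == pytest.approx(4.0)
        assert rr.alpha_from_counts(5, 5) == 1.0

    def test_zero_maternal_is_infinite(self):
        with pytest.warns(UserWarning):
            assert math.isinf(rr.alpha_from_counts(5, 0))

    def test_phased_table_bootstrap(self, rng):
        n = 400
        df = pd.DataFrame(
            {
                "chrom": rng.choice(["chr1", "chr2"], size=n),
                "pos": rng.integers(1, 10_000_000, size=n),
                "consensus": rng.choice(
                    ["paternal", "maternal"], size=n, p=[0.8, 0.2]
                ),
            }
        )
        out = rr.alpha_from_phased(df, uniform_map(), rng=rng)
        lo, hi = out["alpha_ci"]
        assert lo < out["alpha"] < hi
        assert out["fraction_paternal"] == pytest.approx(0.8, abs=0.05)

    def test_bootstrap_deterministic_and_order_free(self, rng):
        n = 120
        df = pd.DataFrame(
            {
                "chrom": rng.choice(["chr1", "chr2"], size=n),
                "pos": rng.integers(1, 10_000_000, size=n),
                "consensus": rng.choice(["paternal", "maternal"], size=n),
            }
        )
        a = rr.alpha_from_phased(df, uniform_map(), rng=np.random.default_rng(9))
        b = rr.alpha_from_phased(
            df.sample(frac=1.0, random_state=4), uniform_map(),
            rng=np.random.default_rng(9),
        )
        assert a["alpha_ci"] == b["alpha_ci"]

    def test_fitted_mode(self, rng):
        out = rr.alpha_fitted(_fit(8, 1.35), _fit(2.4, 0.37), 32.0, 28.2, rng=rng)
        expected = (8 + 1.35 * 32) / (2.4 + 0.37 * 28.2)
        assert out["alpha"] == pytest.approx(expected)


class TestBlockBootstrap:
    def test_refuses_fewer_than_two_nonempty_blocks(self, rng):
        df = pd.DataFrame({"chrom": ["chr1"] * 5, "pos": [10, 20, 30, 40, 50]})
        with pytest.raises(ValueError, match="2 non-empty"):
            rr.block_bootstrap(df, uniform_map(), len, rng=rng)

    def test_mean_ci_covers_truth_at_nominal_rate(self):
        # i.i.d. normal draws spread over 40 blocks: the percentile interval
        # for the mean should cover truth at roughly its nominal 95% rate
        gmap = uniform_map(total_cm=2000.0)
        hits = 0
        reps = 80
        for rep in range(reps):
            rng = np.random.default_rng(rep)
            n = 200
            df = pd.DataFrame(
                {
                    "chrom": rng.choice(["chr1", "chr2"], size=n),
                    "pos": rng.integers(1, 10_000_000, size=n),
                    "value": rng.normal(1.5, 1.0, size=n),
                }
            )
            (lo, hi), _ = rr.block_bootstrap(
                df, gmap, lambda d: d["value"].mean(), n_boot=200, rng=rng
            )
            hits += lo <= 1.5 <= hi
        assert 0.85 <= hits / reps <= 0.995

    def test_unknown_chromosome_rejected(self, rng):
        df = pd.DataFrame({"chrom": ["chrX"], "pos": [5]})
        with pytest.raises(ValueError, match="absent from the map"):
            rr.block_bootstrap(df, uniform_map(), len, rng=rng)


class TestCompartments:
    def test_equal_everything_gives_p_one(self):
        counts = pd.DataFrame(
            {"trio_id": ["a", "a"], "compartment": ["x", "y"], "count": [10, 10]}
        )
        sizes = pd.DataFrame(
            {"trio_id": ["a", "a"], "compartment": ["x", "y"], "bp": [1e6, 1e6]}
        )
        rates, tests = rr.compartment_rates(counts, sizes, {"a": 0.0}, {"a": 0.0})
        assert rates["x"] == rates["y"]
        assert tests[("x", "y")] == 1.0

    def test_one_sided_extreme(self):
        assert rr.poisson_rate_ratio_test(10, 0, 1.0, 1.0) == pytest.approx(
            2 * 0.5**10
        )

    def test_weighted_rate_arithmetic(self):
        counts = pd.DataFrame(
            {"trio_id": ["a", "b"], "compartment": ["x", "x"], "count": [10, 20]}
        )
        sizes = pd.DataFrame(
            {"trio_id": ["a", "b"], "compartment": ["x", "x"], "bp": [1e6, 1e6]}
        )
        rates, _ = rr.compartment_rates(
            counts, sizes, {"a": 0.2, "b": 0.0}, {"a": 0.0, "b": 0.5}
        )
        expected = (10 * 0.8 + 20 / 0.5) / (2 * 2e6)
        assert rates["x"] == pytest.approx(expected)


class TestExponentialMaternalModel:
    def test_identical_predictions_give_zero(self, rng):
        counts = rng.poisson(10, size=20)
        ages = rng.uniform(20, 40, size=20)
        delta = rr.exponential_maternal_aic(
            counts, ages, 0.0, (10.0, 0.0), (10.0, 0.0)
        )
        assert delta == pytest.approx(0.0)

    def test_exponential_data_prefers_exponential(self, rng):
        ages = rng.uniform(20, 45, size=400)
        c0, c1 = 1.0, 0.08
        counts = rng.poisson(c0 * np.exp(c1 * ages))
        b = np.polyfit(ages, c0 * np.exp(c1 * ages), 1)
        delta = rr.exponential_maternal_aic(
            counts, ages, 0.0, (b[1], b[0]), (c0, c1)
        )
        assert delta < 0

    def test_linear_data_prefers_linear(self, rng):
        ages = rng.uniform(20, 45, size=400)
        b0, b1 = 3.0, 0.5
        counts = rng.poisson(b0 + b1 * ages)
        # exponential approximation fitted to the linear trend
        coef = np.polyfit(ages, np.log(b0 + b1 * ages), 1)
        delta = rr.exponential_maternal_aic(
            counts, ages, 0.0, (b0, b1), (np.exp(coef[1]), coef[0])
        )
        assert delta > 0

    def test_nonpositive_means_rejected(self):
        with pytest.raises(ValueError):
            rr.exponential_maternal_aic([1, 2], [10, 20], 0.0, (0.0, 0.0), (1.0, 0.0))


def test_scale_external_params():
    assert rr.scale_external_params(1.0, H=2.0, R=4.0) == 0.5
    with pytest.raises(ValueError):
        rr.scale_external_params(1.0, H=2.0, R=0.0)
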