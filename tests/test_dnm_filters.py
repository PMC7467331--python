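"""Filter battery, cluster detection, 3-haplotype test, accessible genome."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pedmut import dnm_filters as dfil
from pedmut.io_formats import CANDIDATE_COLUMNS, IntervalSet


def brute_force_depth_window(lam, threshold, max_depth=400):
    """Independent scan: doubled-tail Poisson p per depth from summed pmfs."""
    pmf = [math.exp(-lam)]
    for k in range(max_depth):
        pmf.append(pmf[-1] * lam / (k + 1))
    passing = []
    for d in range(max_depth + 1):
        lower = sum(pmf[: d + 1])
        upper = 1.0 - sum(pmf[:d])
        p = min(1.0, 2 * min(lower, upper))
        if p > threshold:
            passing.append(d)
    return min(passing), max(passing)


class TestDepthCutoffs:
    @pytest.mark.parametrize("lam", [10.0, 30.0, 52.3])
    def test_matches_exhaustive_scan(self, lam):
        cut = dfil.depth_cutoffs(lam, 2e-4)
        lo, hi = brute_force_depth_window(lam, 2e-4)
        assert (cut.min_depth, cut.max_depth) == (lo, hi)

    def test_mean_depth_always_passes(self):
        for lam in (5.0, 30.0, 80.0):
            cut = dfil.depth_cutoffs(lam)
            assert cut.passes(round(lam))

    def test_zero_depth_fails_at_lambda_30(self):
        # two-sided p = 2*exp(-30) ~ 1.9e-13, far below the threshold
        cut = dfil.depth_cutoffs(30.0, 2e-4)
        assert not cut.passes(0)
        assert dfil.two_sided_poisson_p(0, 30.0) == pytest.approx(
            2 * math.exp(-30), rel=1e-9
        )

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.5, 2.0])
    def test_threshold_domain(self, bad):
        with pytest.raises(ValueError):
            dfil.depth_cutoffs(30.0, bad)


def make_candidate(**overrides):
    row = {c: None for c in CANDIDATE_COLUMNS}
    row.update(
        trio_id="T0",
        chrom="chr1",
        pos=1000,
        ref="C",
        alt="T",
        qual=500.0,
        child_gt="0/1",
        child_ad_ref=20,
        child_ad_alt=20,
        child_dp=40,
        child_gq=99,
        father_gt="0/0",
        father_ad_ref=30,
        father_ad_alt=0,
        father_dp=30,
        father_gq=99,
        mother_gt="0/0",
        mother_ad_ref=30,
        mother_ad_alt=0,
        mother_dp=30,
        mother_gq=99,
        QD=20.0,
        FS=1.0,
        MQ=60.0,
        MQRankSum=0.0,
        ReadPosRankSum=0.0,
        SOR=1.0,
        known_variant=False,
        other_family_alt=False,
        ctx5="A",
        ctx3="A",
        f2_observed="",
        readbacked_phase="NA",
        transmission_phase="NA",
    )
    row.update(overrides)
    return row


def run_filters(rows, **kwargs):
    df = pd.DataFrame(rows)
    return dfil.apply_site_filters(df, dfil.FilterConfig(), **kwargs)


class TestSiteFilters:
    def test_clean_candidate_passes(self):
        passed, tally = run_filters([make_candidate()])
        assert len(passed) == 1
        assert sum(tally.values()) == 0

    def test_ad_alt_threshold_is_strict(self):
        # "greater than 3": exactly 3 ALT reads fails, 4 passes
        # (low depth keeps the allele-balance test satisfied in both cases)
        passed, tally = run_filters(
            [make_candidate(child_ad_alt=3, child_ad_ref=5, child_dp=8)]
        )
        assert len(passed) == 0
        assert tally["child_ad_alt"] == 1
        assert tally["allele_balance"] == 0
        passed, _ = run_filters(
            [make_candidate(child_ad_alt=4, child_ad_ref=6, child_dp=10)]
        )
        assert len(passed) == 1

    def test_allele_balance_rejects_extreme_skew(self):
        # 2 alt of 40 reads: doubled-tail binomial p ~ 3e-9 < 0.05
        passed, tally = run_filters(
            [make_candidate(child_ad_alt=2, child_ad_ref=38)]
        )
        assert tally["allele_balance"] == 1
        p = dfil.two_sided_binom_p(2, 40)
        assert p < 0.05
        assert p == pytest.approx(2 * stats.binom.cdf(2, 40, 0.5))

    def test_allele_balance_boundary_counts_as_pass(self):
        # find a (k, n) whose doubled-tail p is just >= 0.05 and check it passes
        k, n = 13, 40  # p ~ 0.038 -> fails; 14/40 ~ 0.08 -> passes
        assert dfil.two_sided_binom_p(k, n) < 0.05
        assert dfil.two_sided_binom_p(14, n) >= 0.05
        passed, _ = run_filters([make_candidate(child_ad_alt=14, child_ad_ref=26)])
        assert len(passed) == 1

    def test_qual_strictly_greater_than_100(self):
        _, tally = run_filters([make_candidate(qual=100.0)])
        assert tally["qual"] == 1

    def test_parent_filters(self):
        # ALT reads in both parents: fails; in only one: passes
        _, tally = run_filters(
            [make_candidate(father_ad_alt=1, mother_ad_alt=2)]
        )
        assert tally["parent_ad"] == 1
        passed, _ = run_filters([make_candidate(father_ad_alt=5, mother_ad_alt=0)])
        assert len(passed) == 1
        _, tally = run_filters([make_candidate(mother_gq=40)])
        assert tally["parent_gq"] == 1

    def test_known_variant_and_cross_family_exclusion(self):
        _, tally = run_filters(
            [
                make_candidate(known_variant=True),
                make_candidate(other_family_alt=True),
            ]
        )
        assert tally["known_variant"] == 1
        assert tally["other_family_allele"] == 1

    def test_missing_metric_counted_separately(self):
        _, tally = run_filters([make_candidate(child_gq=None, qual=None)])
        assert tally["missing_metric"] == 1
        assert tally["qual"] == 0
        assert tally["child_gq"] == 0

    def test_missing_ranksum_annotations_pass_hard_filters(self):
        passed, tally = run_filters(
            [make_candidate(MQRankSum=None, ReadPosRankSum=None)]
        )
        assert len(passed) == 1
        assert tally["missing_metric"] == 0

    def test_trio_depth_window(self):
        cuts = {
            role: dfil.depth_cutoffs(30.0, individual_id=role)
            for role in ("child", "father", "mother")
        }
        passed, _ = run_filters([make_candidate()], depth_cutoffs_by_member=cuts)
        assert len(passed) == 1
        _, tally = run_filters(
            [make_candidate(father_dp=150, father_ad_ref=150)],
            depth_cutoffs_by_member=cuts,
        )
        assert tally["trio_depth"] == 1

    def test_conjunctive_surviving_set_order_free(self, small_cohort):
        # filters are conjunctive: a doubly-failing row is removed exactly once
        rows = [
            make_candidate(),
            make_candidate(qual=50.0, child_gq=10),
            make_candidate(child_ad_alt=1, child_ad_ref=39, mother_gq=5),
        ]
        passed, tally = run_filters(rows)
        assert len(passed) == 1
        # the synthetic cohort's candidate tables pass by construction
        passed_cohort, _ = dfil.apply_site_filters(
            small_cohort.candidates, dfil.FilterConfig()
        )
        assert len(passed_cohort) == len(small_cohort.candidates)


class TestClusters:
    def _positions(self, positions, chrom="chr1"):
        return pd.DataFrame(
            {
                "trio_id": "T0",
                "chrom": chrom,
                "pos": positions,
            }
        )

    def test_window_is_strict(self):
        out = dfil.detect_clusters(self._positions([100, 150, 300]))
        sizes = dict(zip(out["pos"], out["cluster_size"]))
        assert sizes == {100: 2, 150: 2, 300: 1}  # gap of 150 >= 100 splits

    def test_chain_of_99bp_gaps(self):
        out = dfil.detect_clusters(self._positions([1, 100, 199]))
        assert set(out["cluster_size"]) == {3}

    def test_exact_100bp_gap_does_not_cluster(self):
        out = dfil.detect_clusters(self._positions([1, 101]))
        assert set(out["cluster_size"]) == {1}

    def test_single_dnm(self):
        out = dfil.detect_clusters(self._positions([42]))
        assert list(out["cluster_size"]) == [1]

    def test_permutation_invariance(self, rng):
        pos = rng.integers(1, 100_000, size=200)
        df = self._positions(pos)
        shuffled = df.sample(frac=1.0, random_state=3)
        a = dfil.detect_clusters(df).set_index("pos")["cluster_size"]
        b = dfil.detect_clusters(shuffled).set_index("pos")["cluster_size"]
        pd.testing.assert_series_equal(a.sort_index(), b.sort_index())

    def test_grouped_detection_matches_per_trio(self, rng):
        df = pd.DataFrame(
            {
                "trio_id": rng.choice(["a", "b", "c"], size=300),
                "chrom": rng.choice(["chr1", "chr2"], size=300),
                "pos": rng.integers(1, 50_000, size=300),
            }
        )
        grouped = dfil.detect_clusters_by_trio(df)
        per_trio = pd.concat(
            [dfil.detect_clusters(sub) for _, sub in df.groupby("trio_id")]
        )
        key = ["trio_id", "chrom", "pos"]
        a = grouped.sort_values(key)["cluster_size"].to_numpy()
        b = per_trio.sort_values(key)["cluster_size"].to_numpy()
        assert (a == b).all()

    def test_remove_large_clusters(self):
        df = self._positions([10, 50, 90, 1000, 1050, 5000])
        out = dfil.remove_large_clusters(dfil.detect_clusters(df))
        assert sorted(out["pos"]) == [1000, 1050, 5000]  # triplet gone, doublet kept

    def test_no_clusters_is_identity(self):
        df = self._positions([1, 1000, 2000])
        out = dfil.remove_large_clusters(dfil.detect_clusters(df))
        assert sorted(out["pos"]) == [1, 1000, 2000]


class TestThreeHaplotypeTest:
    def test_two_haplotypes_pass(self):
        pairs = {"snp1": [("ref", "ref")] * 5 + [("alt", "alt")] * 5}
        assert dfil.three_haplotype_test(pairs) == (True, True)

    def test_three_supported_haplotypes_fail(self):
        pairs = {
            "snp1": [("ref", "ref")] * 2 + [("alt", "ref")] * 2 + [("alt", "alt")] * 2
        }
        assert dfil.three_haplotype_test(pairs) == (False, True)

    def test_single_read_third_haplotype_not_counted(self):
        pairs = {
            "snp1": [("ref", "ref")] * 4 + [("alt", "alt")] * 4 + [("alt", "ref")]
        }
        assert dfil.three_haplotype_test(pairs) == (True, True)

    def test_no_eligible_snp_passes_vacuously_flagged(self):
        pairs = {"snp1": [("ref", "ref")] * 2 + [("alt", "ref")] * 2 + [("alt", "alt")] * 2}
        passed, tested = dfil.three_haplotype_test(
            pairs, snp_eligible={"snp1": False}
        )
        assert passed and not tested


def brute_force_size(intervals, size=1000):
    present = [False] * size
    for _, s, e in intervals:
        for b in range(s, min(e, size)):
            present[b] = True
    return sum(present)


class TestAccessibleGenome:
    def test_identical_sets(self):
        s = IntervalSet([("chr1", 0, 500)])
        acc = dfil.accessible_genome({"child": s, "father": s, "mother": s})
        assert acc.accessible_bp == 500

    def test_staggered_toy_genome_matches_brute_force(self):
        child = IntervalSet([("chr1", 0, 600), ("chr1", 650, 900)])
        father = IntervalSet([("chr1", 100, 700)])
        mother = IntervalSet([("chr1", 50, 620), ("chr1", 660, 1000)])
        ortho = IntervalSet([("chr1", 0, 400)])
        rep = IntervalSet([("chr1", 300, 680)])
        acc = dfil.accessible_genome(
            {"child": child, "father": father, "mother": mother},
            orthologous=ortho,
            repeats=rep,
        )
        inter = child.intersect(father).intersect(mother)
        assert acc.accessible_bp == brute_force_size(inter.to_tuples())
        a = dfil.AccessibleGenome
        assert acc.compartments[a.ORTH_REP] == brute_force_size(
            inter.intersect(ortho).intersect(rep).to_tuples()
        )
        assert acc.compartments[a.NONORTH_NONREP] == brute_force_size(
            inter.subtract(ortho).subtract(rep).to_tuples()
        )

    def test_compartments_partition_exactly(self, rng):
        def rand_set():
            ivs = []
            for _ in range(rng.integers(1, 6)):
                s = int(rng.integers(0, 900))
                ivs.append(("chr1", s, s + int(rng.integers(1, 120))))
            return IntervalSet(ivs)

        for _ in range(20):
            acc = dfil.accessible_genome(
                {"c": rand_set(), "f": rand_set(), "m": rand_set()},
                orthologous=rand_set(),
                repeats=rand_set(),
                known_variant_mask=rand_set(),
            )
            assert sum(acc.compartments.values()) == acc.accessible_bp

    def test_empty_callable_warns(self):
        a = IntervalSet([("chr1", 0, 10)])
        b = IntervalSet([("chr1", 20, 30)])
        with pytest.warns(UserWarning, match="empty accessible"):
            acc = dfil.accessible_genome({"c": a, "f": b, "m": a})
        assert acc.accessible_bp == 0
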