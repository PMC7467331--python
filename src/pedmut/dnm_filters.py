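"""Candidate de novo mutation (DNM) filtering.

A candidate DNM is a Mendelian-violation SNP: the child heterozygous for an
ALT allele, both parents homozygous reference.  Nearly all such candidates are
artifacts, so they are run through a conjunctive battery of site-, child- and
parent-level filters, a mutation-cluster screen, and (for insertion
simulations) a 3-haplotype phase-consistency test.  The module also computes
the per-trio accessible genome and its orthologous/repeat compartments, the
denominators of every rate downstream.

Exact-test convention used throughout: the two-sided p-value of a discrete
test is min(1, 2*min(lower tail, upper tail)) with the observed point included
in both tails.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import IntervalSet


@dataclass
class FilterConfig:
    """Thresholds of the DNM calling filter battery.

    Defaults implement: trio depth inside the two-sided Poisson acceptance
    region at p > 2e-4; QUAL > 100; GATK hard filters; child GQ > 40,
    ALT allelic depth strictly greater than 3, allele-balance binomial
    p >= 0.05; parental ALT depth 0 in at least one parent and GQ > 40 in
    both; exclusion of known variants and of alleles seen in unrelated
    families; removal of clusters of 3 or more DNMs within 100 bp chains.
    """

    depth_p_threshold: float = 2e-4
    qual_min: float = 100.0
    qd_min: float = 2.0
    fs_max: float = 60.0
    mq_min: float = 40.0
    mqranksum_min: float = -12.5
    readposranksum_min: float = -8.0
    sor_max: float = 3.0
    gq_min_child: float = 40.0
    ad_alt_min_child: int = 3  # strict: AD_alt must exceed this
    ab_p_min: float = 0.05
    gq_min_parent: float = 40.0
    cluster_window: int = 100
    cluster_remove_min_size: int = 3


@dataclass
class DepthCutoffs:
    """Acceptance region of the two-sided Poisson depth test for one individual."""

    individual_id: str
    lam: float
    min_depth: int
    max_depth: int

    def passes(self, depth) -> np.ndarray:
        depth = np.asarray(depth)
        return (depth >= self.min_depth) & (depth <= self.max_depth)


def two_sided_poisson_p(depth, lam: float) -> np.ndarray:
    """Doubled-tail exact Poisson p-value, observed point in both tails."""
    depth = np.asarray(depth)
    lower = stats.poisson.cdf(depth, lam)
    upper = stats.poisson.sf(depth - 1, lam)
    return np.minimum(1.0, 2.0 * np.minimum(lower, upper))


def two_sided_binom_p(k, n, p0: float = 0.5) -> np.ndarray:
    """Doubled-tail exact binomial p-value, observed point in both tails."""
    k = np.asarray(k)
    n = np.asarray(n)
    lower = stats.binom.cdf(k, n, p0)
    upper = stats.binom.sf(k - 1, n, p0)
    return np.minimum(1.0, 2.0 * np.minimum(lower, upper))


def depth_cutoffs(
    lam: float, p_threshold: float = 2e-4, individual_id: str = ""
) -> DepthCutoffs:
    """Largest depth interval [min, max] whose two-sided Poisson p exceeds p_threshold.

    Depths outside the interval are in the rejection region of the test with
    null mean ``lam`` (the individual's mean coverage).
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    if not 0 < p_threshold < 1:
        raise ValueError("p_threshold must lie in (0, 1)")
    upper_scan = int(np.ceil(lam + 20 * np.sqrt(lam) + 20))
    depths = np.arange(0, upper_scan + 1)
    ok = two_sided_poisson_p(depths, lam) > p_threshold
    if not ok.any():
        raise ValueError("empty acceptance region")
    passing = depths[ok]
    return DepthCutoffs(individual_id, lam, int(passing.min()), int(passing.max()))


# Fixed presentation order of the filter tally.
FILTER_ORDER = [
    "missing_metric",
    "biallelic_snv",
    "qual",
    "hard_filters",
    "trio_depth",
    "child_gq",
    "child_ad_alt",
    "allele_balance",
    "parent_ad",
    "parent_gq",
    "known_variant",
    "other_family_allele",
]

_REQUIRED_METRICS = [
    "qual",
    "child_ad_ref",
    "child_ad_alt",
    "child_dp",
    "child_gq",
    "father_ad_alt",
    "father_dp",
    "father_gq",
    "mother_ad_alt",
    "mother_dp",
    "mother_gq",
    "QD",
    "FS",
    "MQ",
    "SOR",
]


def apply_site_filters(
    candidates: pd.DataFrame,
    config: FilterConfig,
    depth_cutoffs_by_member: dict[str, DepthCutoffs] | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the full conjunctive filter battery to a candidate table.

    ``depth_cutoffs_by_member`` maps the roles ``child``/``father``/``mother``
    to per-individual depth acceptance regions; if omitted the trio depth
    filter is skipped (e.g. when callable regions were already depth-screened).

    Returns the surviving candidates and a tally of removals per filter, in
    fixed presentation order.  Filters are conjunctive, so the surviving set
    does not depend on the order.  A candidate missing any required metric is
    rejected with reason ``missing_metric`` and counted separately.

    MQRankSum and ReadPosRankSum are rank-sum annotations that GATK emits only
    at sites with both ref and alt reads; a missing value there passes the
    corresponding hard filter rather than being treated as a missing metric.
    """
    df = candidates
    n = len(df)
    fails = {name: np.zeros(n, dtype=bool) for name in FILTER_ORDER}

    missing = np.zeros(n, dtype=bool)
    for col in _REQUIRED_METRICS:
        missing |= pd.isna(df[col]).to_numpy()
    fails["missing_metric"] = missing

    ref = df["ref"].astype(str)
    alt = df["alt"].astype(str)
    fails["biallelic_snv"] = ~(
        ref.isin(list("ACGT")) & alt.isin(list("ACGT")) & (ref != alt)
    ).to_numpy()

    with np.errstate(invalid="ignore"):
        fails["qual"] = ~(df["qual"].to_numpy(float) > config.qual_min)

        hard_ok = (
            (df["QD"].to_numpy(float) > config.qd_min)
            & (df["FS"].to_numpy(float) < config.fs_max)
            & (df["MQ"].to_numpy(float) > config.mq_min)
            & (df["SOR"].to_numpy(float) < config.sor_max)
        )
        # rank-sum annotations may be absent at hom-ref-parent sites; absent passes
        mqrs = df["MQRankSum"].to_numpy(float)
        rprs = df["ReadPosRankSum"].to_numpy(float)
        hard_ok &= np.isnan(mqrs) | (mqrs > config.mqranksum_min)
        hard_ok &= np.isnan(rprs) | (rprs > config.readposranksum_min)
        fails["hard_filters"] = ~hard_ok

        if depth_cutoffs_by_member is not None:
            depth_ok = np.ones(n, dtype=bool)
            for role in ("child", "father", "mother"):
                cut = depth_cutoffs_by_member[role]
                depth_ok &= cut.passes(df[f"{role}_dp"].to_numpy(float))
            fails["trio_depth"] = ~depth_ok

        fails["child_gq"] = ~(df["child_gq"].to_numpy(float) > config.gq_min_child)
        fails["child_ad_alt"] = ~(
            df["child_ad_alt"].to_numpy(float) > config.ad_alt_min_child
        )

        ad_ref = df["child_ad_ref"].to_numpy(float)
        ad_alt = df["child_ad_alt"].to_numpy(float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ab_p = two_sided_binom_p(
                np.nan_to_num(ad_alt, nan=0.0).astype(int),
                np.nan_to_num(ad_alt + ad_ref, nan=0.0).astype(int),
            )
        fails["allele_balance"] = ~(ab_p >= config.ab_p_min)

        father_ad = df["father_ad_alt"].to_numpy(float)
        mother_ad = df["mother_ad_alt"].to_numpy(float)
        fails["parent_ad"] = ~((father_ad == 0) | (mother_ad == 0))
        fails["parent_gq"] = ~(
            (df["father_gq"].to_numpy(float) > config.gq_min_parent)
            & (df["mother_gq"].to_numpy(float) > config.gq_min_parent)
        )

    fails["known_variant"] = df["known_variant"].fillna(False).to_numpy(bool)
    fails["other_family_allele"] = df["other_family_alt"].fillna(False).to_numpy(bool)

    # a row missing metrics is counted only under missing_metric
    for name in FILTER_ORDER[1:]:
        fails[name] &= ~missing

    any_fail = np.zeros(n, dtype=bool)
    tally: dict[str, int] = {}
    for name in FILTER_ORDER:
        if name == "trio_depth" and depth_cutoffs_by_member is None:
            tally[name] = 0
            continue
        tally[name] = int(fails[name].sum())
        any_fail |= fails[name]

    return df.loc[~any_fail].copy(), tally


def detect_clusters(candidates: pd.DataFrame, window: int = 100) -> pd.DataFrame:
    """Annotate candidates of one trio with cluster_id and cluster_size.

    A cluster is a maximal chain of DNMs on one chromosome in which consecutive
    members (in position order) are strictly fewer than ``window`` bp apart.
    Singletons get cluster size 1.  Input order does not matter.
    """
    df = candidates.sort_values(["chrom", "pos"], kind="mergesort").copy()
    if df.empty:
        df["cluster_id"] = pd.Series(dtype=int)
        df["cluster_size"] = pd.Series(dtype=int)
        return df
    chrom = df["chrom"].to_numpy()
    pos = df["pos"].to_numpy()
    new_cluster = np.ones(len(df), dtype=bool)
    same_chrom = chrom[1:] == chrom[:-1]
    close = (pos[1:] - pos[:-1]) < window
    new_cluster[1:] = ~(same_chrom & close)
    cluster_id = np.cumsum(new_cluster) - 1
    df["cluster_id"] = cluster_id
    sizes = pd.Series(cluster_id).value_counts()
    df["cluster_size"] = sizes.reindex(cluster_id).to_numpy()
    return df


def detect_clusters_by_trio(candidates: pd.DataFrame, window: int = 100) -> pd.DataFrame:
    """detect_clusters applied per trio in one pass (clusters never span trios)."""
    df = candidates.sort_values(["trio_id", "chrom", "pos"], kind="mergesort").copy()
    if df.empty:
        df["cluster_id"] = pd.Series(dtype=int)
        df["cluster_size"] = pd.Series(dtype=int)
        return df
    trio = df["trio_id"].to_numpy()
    chrom = df["chrom"].to_numpy()
    pos = df["pos"].to_numpy()
    new_cluster = np.ones(len(df), dtype=bool)
    same = (trio[1:] == trio[:-1]) & (chrom[1:] == chrom[:-1])
    close = (pos[1:] - pos[:-1]) < window
    new_cluster[1:] = ~(same & close)
    cluster_id = np.cumsum(new_cluster) - 1
    df["cluster_id"] = cluster_id
    sizes = pd.Series(cluster_id).value_counts()
    df["cluster_size"] = sizes.reindex(cluster_id).to_numpy()
    return df


def remove_large_clusters(
    candidates: pd.DataFrame, min_size: int = 3
) -> pd.DataFrame:
    """Drop all members of clusters of size >= min_size.

    Doublets and singletons are retained, keeping their cluster_size label for
    the downstream singlet/doublet FDR stratification.
    """
    if "cluster_size" not in candidates.columns:
        raise ValueError("run detect_clusters first")
    return candidates.loc[candidates["cluster_size"] < min_size].copy()


def three_haplotype_test(
    read_pairs_by_snp: dict[str, list[tuple[str, str]]],
    snp_eligible: dict[str, bool] | None = None,
    min_reads_per_haplotype: int = 2,
) -> tuple[bool, bool]:
    """Phase-consistency screen for inserted DNMs, analogous to the 4-gamete test.

    ``read_pairs_by_snp`` maps each nearby comparison heterozygous SNP to the
    list of (focal allele, SNP allele) calls observed on individual reads
    spanning both sites.  ``snp_eligible`` marks comparison SNPs that passed
    the prefilters (ALT AD >= 3 and allele-balance binomial p > 0.05); absent
    means eligible.  A haplotype is counted only when supported by at least
    ``min_reads_per_haplotype`` reads.

    Returns (passed, tested).  With no eligible comparison SNP the site passes
    vacuously and is flagged untested.
    """
    tested = False
    for snp_id, pairs in read_pairs_by_snp.items():
        if snp_eligible is not None and not snp_eligible.get(snp_id, True):
            continue
        tested = True
        counts: dict[tuple[str, str], int] = {}
        for pair in pairs:
            counts[pair] = counts.get(pair, 0) + 1
        supported = sum(1 for c in counts.values() if c >= min_reads_per_haplotype)
        if supported >= 3:
            return False, True
    return True, tested


@dataclass
class AccessibleGenome:
    """Per-trio accessible haploid genome and its 4 compartments (bp)."""

    accessible: IntervalSet
    accessible_bp: int
    compartments: dict[str, int] = field(default_factory=dict)

    ORTH_REP = "orthologous_repetitive"
    ORTH_NONREP = "orthologous_nonrepetitive"
    NONORTH_REP = "nonorthologous_repetitive"
    NONORTH_NONREP = "nonorthologous_nonrepetitive"


def accessible_genome(
    member_callable: dict[str, IntervalSet],
    orthologous: IntervalSet | None = None,
    repeats: IntervalSet | None = None,
    parental_variant_mask: IntervalSet | None = None,
    known_variant_mask: IntervalSet | None = None,
) -> AccessibleGenome:
    """Intersect callable regions across the trio and partition into compartments.

    The accessible haploid genome is the intersection of the members' callable
    sets minus sites where a parent carries a non-reference genotype and minus
    known-variant sites.  Intersections with the orthologous and repeat sets
    yield the 4 compartments, which partition the accessible genome exactly.
    """
    members = list(member_callable.values())
    if not members:
        raise ValueError("no trio members")
    acc = members[0]
    for other in members[1:]:
        acc = acc.intersect(other)
    for mask in (parental_variant_mask, known_variant_mask):
        if mask is not None:
            acc = acc.subtract(mask)
    if acc.total_bp == 0:
        warnings.warn("empty accessible genome for trio", stacklevel=2)

    result = AccessibleGenome(accessible=acc, accessible_bp=acc.total_bp)
    orth = orthologous if orthologous is not None else IntervalSet()
    rep = repeats if repeats is not None else IntervalSet()
    in_orth = acc.intersect(orth)
    out_orth = acc.subtract(orth)
    result.compartments = {
        AccessibleGenome.ORTH_REP: in_orth.intersect(rep).total_bp,
        AccessibleGenome.ORTH_NONREP: in_orth.subtract(rep).total_bp,
        AccessibleGenome.NONORTH_REP: out_orth.intersect(rep).total_bp,
        AccessibleGenome.NONORTH_NONREP: out_orth.subtract(rep).total_bp,
    }
    return result
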