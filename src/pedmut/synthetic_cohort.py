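"""Synthetic multigeneration cohorts with known ground truth.

The generator emulates the statistical structure the inference chain assumes,
on a miniature genome:

* per-trio true DNM counts are Poisson with mean linear in the parental age
  at conception, separately per sex (the male intercept/slope several-fold
  the female's, giving a male bias around 4);
* each true DNM has a parent of origin, a position uniform over the genome,
  and a 7-type mutation class drawn from a configurable spectrum;
* a genuine DNM is observed in each F2 independently with a per-pair marginal
  probability q (the product of Mendelian transmission and calling power, the
  quantity the transmission FDR model identifies);
* false positives are injected so the realized contamination of each trio's
  calls equals fdr_true, and never transmit; a fraction fnr_true of true DNMs
  is deleted before output; artifact clusters of 3+ co-located calls are
  injected separately and also never transmit;
* read-backed and transmission phase evidence point to the true parent, with
  configurable availability;
* companion tables mimic the two error-rate simulations: per F1-F2 counts of
  simulated transmissions (for estimating q) and a per-trio simulated-DNM
  filter table with injected defects (for estimating the FNR).

Every quantity the pipeline later estimates is recorded in a truth ledger.
The miniature genome compresses physical size (two 10 Mb chromosomes) but
keeps a genome-scale genetic length (1750 cM per chromosome, ~3500 cM total)
so that 50 cM block bootstraps operate on a realistic number of blocks.

The metric distributions at simulated sites (depths, qualities, allele
balances) are stand-ins chosen to be comfortably inside or outside the filter
thresholds; they are configurable and are not estimates of any real
sequencing run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dnm_filters import FilterConfig, apply_site_filters, two_sided_binom_p
from .io_formats import CANDIDATE_COLUMNS, GeneticMap, Individual, Pedigree

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: (pyrimidine-strand ref, alt, allowed 3' bases) per mutation type
_TYPE_TEMPLATES = {
    "C>A": ("C", "A", "ACGT"),
    "C>G": ("C", "G", "ACGT"),
    "T>A": ("T", "A", "ACGT"),
    "T>C": ("T", "C", "ACGT"),
    "T>G": ("T", "G", "ACGT"),
    "CpG>TpG": ("C", "T", "G"),
    "CpH>TpH": ("C", "T", "ACT"),
}


@dataclass
class CohortSpec:
    """Study conditions of a synthetic cohort.

    Defaults describe a human-like cohort: Poisson intercepts/slopes on the
    full-genome count scale giving ~50 paternal and ~13 maternal DNMs at
    typical reproductive ages (alpha ~ 4), per-trio false discovery ~0.2 and
    false negative ~0.10 rates, and per F1-F2 observation probabilities in
    (0.4, 0.55).
    """

    n_f1: int = 12
    f2_count_probs: tuple[float, float, float] = (0.0, 0.7, 0.3)  # P(0/1/2 F2s)
    species: str = "synthetic"
    beta0_m: float = 8.0
    beta1_m: float = 1.35
    beta0_f: float = 2.4
    beta1_f: float = 0.37
    gestation: float = 0.767
    father_age_range: tuple[float, float] = (18.0, 45.0)
    mother_age_range: tuple[float, float] = (18.0, 42.0)
    q_range: tuple[float, float] = (0.40, 0.55)
    fdr_true: float = 0.20
    fnr_true: float = 0.10
    doublet_fraction: float = 0.04  # fraction of true DNMs placed in 2-DNM clusters
    triplet_fp_rate: float = 0.25  # artifact 3-DNM clusters per trio (Poisson mean)
    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 10_000_000, "chr2": 10_000_000}
    )
    cm_per_chrom: float = 1750.0
    orthologous_fraction: float = 1.0
    mutation_type_probs: tuple[float, ...] = (
        0.09,  # C>A
        0.09,  # C>G
        0.06,  # T>A
        0.28,  # T>C
        0.06,  # T>G
        0.18,  # CpG>TpG
        0.24,  # CpH>TpH
    )
    p_readbacked: float = 0.40
    p_transmission_phase: float = 0.90
    missing_mother_age_fraction: float = 0.0
    mean_depth: float = 30.0
    n_sim_transmission: int = 1000  # simulated DNMs per F1-F2 pair (q estimation)
    n_sim_fnr: int = 20000  # simulated DNMs per trio (FNR estimation)
    seed: int = 0

    def __post_init__(self) -> None:
        probs = np.asarray(self.mutation_type_probs, dtype=float)
        if probs.size != 7 or abs(probs.sum() - 1.0) > 1e-9 or (probs < 0).any():
            raise ValueError("mutation_type_probs must be a 7-vector summing to 1")
        if abs(sum(self.f2_count_probs) - 1.0) > 1e-9:
            raise ValueError("f2_count_probs must sum to 1")
        for p in (self.fdr_true, self.fnr_true, self.p_readbacked,
                  self.p_transmission_phase, self.orthologous_fraction):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        for age_range, (b0, b1) in (
            (self.father_age_range, (self.beta0_m, self.beta1_m)),
            (self.mother_age_range, (self.beta0_f, self.beta1_f)),
        ):
            for age in age_range:
                if b0 + b1 * age <= 0:
                    raise ValueError(
                        f"infeasible spec: expected count {b0} + {b1}*{age} <= 0"
                    )

    @property
    def haploid_size(self) -> int:
        return sum(self.chrom_sizes.values())

    @property
    def orthologous_size(self) -> float:
        return self.orthologous_fraction * self.haploid_size

    def genetic_map(self) -> GeneticMap:
        """Uniform-rate map: cm_per_chrom over each chromosome."""
        return GeneticMap(
            {
                chrom: (
                    np.array([1.0, float(size)]),
                    np.array([0.0, self.cm_per_chrom]),
                )
                for chrom, size in self.chrom_sizes.items()
            }
        )


@dataclass
class SimulatedCohort:
    spec: CohortSpec
    pedigree: Pedigree
    candidates: pd.DataFrame
    truth: pd.DataFrame
    transmission_sim: pd.DataFrame  # trio_id, f2_index, n_eligible, n_observed
    filter_sim: pd.DataFrame  # simulated-DNM filter table across trios
    q_true: dict[tuple[str, int], float]
    ages: pd.DataFrame  # trio_id, father_age, mother_age (conception; NaN if missing)

    @property
    def genetic_map(self) -> GeneticMap:
        return self.spec.genetic_map()


def _draw_mutation_types(n: int, probs, rng: np.random.Generator) -> pd.DataFrame:
    """ref/alt/context consistent with drawn 7-type labels; strand randomized."""
    types = list(_TYPE_TEMPLATES)
    chosen = rng.choice(len(types), size=n, p=np.asarray(probs, dtype=float))
    ref = np.empty(n, dtype="<U1")
    alt = np.empty(n, dtype="<U1")
    ctx5 = rng.choice(list("ACGT"), size=n)
    ctx3 = np.empty(n, dtype="<U1")
    for i, t_idx in enumerate(chosen):
        r, a, allowed3 = _TYPE_TEMPLATES[types[t_idx]]
        ref[i], alt[i] = r, a
        ctx3[i] = allowed3[rng.integers(len(allowed3))]
    flip = rng.random(n) < 0.5
    for i in np.flatnonzero(flip):
        ref[i], alt[i] = _COMPLEMENT[ref[i]], _COMPLEMENT[alt[i]]
        ctx5[i], ctx3[i] = _COMPLEMENT[ctx3[i]], _COMPLEMENT[ctx5[i]]
    return pd.DataFrame(
        {"ref": ref, "alt": alt, "ctx5": ctx5, "ctx3": ctx3,
         "true_type": [types[i] for i in chosen]}
    )


def _passing_metric_arrays(
    n: int, mean_depth: float, rng: np.random.Generator
) -> dict:
    """Genotype/site metric arrays comfortably inside every filter threshold."""
    dp = np.maximum(rng.poisson(mean_depth, size=n), 10)
    lo = np.maximum((0.35 * dp).astype(int) + 1, 4)
    hi = np.maximum((0.65 * dp).astype(int), lo)
    ad_alt = rng.integers(lo, hi + 1)
    # guarantee the allele-balance exact test passes
    for _ in range(20):
        p = two_sided_binom_p(ad_alt, dp)
        bad = (p < 0.05) | (ad_alt <= 3)
        if not bad.any():
            break
        ad_alt[bad] = np.maximum(dp[bad] // 2, 4)
    parent_dp = rng.poisson(mean_depth, size=(2, n))
    return {
        "qual": rng.uniform(300, 1500, size=n).round(2),
        "child_gt": np.full(n, "0/1"),
        "child_ad_ref": dp - ad_alt,
        "child_ad_alt": ad_alt,
        "child_dp": dp,
        "child_gq": rng.integers(60, 100, size=n),
        "father_gt": np.full(n, "0/0"),
        "father_ad_ref": parent_dp[0],
        "father_ad_alt": np.zeros(n, dtype=int),
        "father_dp": parent_dp[0],
        "father_gq": rng.integers(60, 100, size=n),
        "mother_gt": np.full(n, "0/0"),
        "mother_ad_ref": parent_dp[1],
        "mother_ad_alt": np.zeros(n, dtype=int),
        "mother_dp": parent_dp[1],
        "mother_gq": rng.integers(60, 100, size=n),
        "QD": rng.uniform(15, 30, size=n).round(2),
        "FS": rng.uniform(0, 5, size=n).round(3),
        "MQ": rng.uniform(55, 62, size=n).round(2),
        "MQRankSum": rng.normal(0, 1, size=n).round(3),
        "ReadPosRankSum": rng.normal(0, 1, size=n).round(3),
        "SOR": rng.uniform(0.3, 1.5, size=n).round(3),
        "known_variant": np.zeros(n, dtype=bool),
        "other_family_alt": np.zeros(n, dtype=bool),
    }


def _passing_metrics(n: int, mean_depth: float, rng: np.random.Generator) -> pd.DataFrame:
    return pd.DataFrame(_passing_metric_arrays(n, mean_depth, rng))


def _draw_positions(
    n: int, spec: CohortSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    chroms = list(spec.chrom_sizes)
    sizes = np.array([spec.chrom_sizes[c] for c in chroms], dtype=float)
    which = rng.choice(len(chroms), size=n, p=sizes / sizes.sum())
    pos = np.empty(n, dtype=int)
    for i, c in enumerate(chroms):
        mask = which == i
        pos[mask] = rng.integers(1, spec.chrom_sizes[c] + 1, size=int(mask.sum()))
    return np.asarray(chroms, dtype=object)[which], pos


def simulate_cohort(spec: CohortSpec) -> SimulatedCohort:
    """Generate one cohort (pedigree, candidate calls, truth ledger and the two
    error-simulation companion tables) under the given study conditions.

    Output is a deterministic function of ``spec`` (including its seed).
    """
    root = np.random.SeedSequence(spec.seed)
    rng_ages, rng_counts, rng_pos, rng_types, rng_obs, rng_metrics, rng_sim = (
        np.random.default_rng(s) for s in root.spawn(7)
    )

    individuals: list[Individual] = []
    candidate_rows: list[pd.DataFrame] = []
    truth_rows: list[pd.DataFrame] = []
    trans_rows = []
    q_true: dict[tuple[str, int], float] = {}
    age_rows = []

    for i in range(spec.n_f1):
        trio = f"T{i:03d}"
        father_age = rng_ages.uniform(*spec.father_age_range)
        mother_age = rng_ages.uniform(*spec.mother_age_range)
        mother_missing = rng_ages.random() < spec.missing_mother_age_fraction
        m_f2 = rng_ages.choice(3, p=spec.f2_count_probs)
        age_rows.append(
            {
                "trio_id": trio,
                "father_age": father_age,
                "mother_age": np.nan if mother_missing else mother_age,
                "m_f2": m_f2,
            }
        )
        individuals.append(Individual(f"{trio}_P0_f", "male", generation="P0",
                                      mean_depth=spec.mean_depth))
        individuals.append(Individual(f"{trio}_P0_m", "female", generation="P0",
                                      mean_depth=spec.mean_depth))
        f1_depth = float(max(rng_ages.normal(spec.mean_depth, 4.0), 10.0))
        individuals.append(
            Individual(
                f"{trio}_F1",
                "male" if rng_ages.random() < 0.5 else "female",
                father_id=f"{trio}_P0_f",
                mother_id=f"{trio}_P0_m",
                generation="F1",
                mean_depth=round(f1_depth, 2),
                age_father_at_conception=round(father_age, 2),
                age_mother_at_conception=None if mother_missing else round(mother_age, 2),
            )
        )
        f1 = individuals[-1]
        for j in range(m_f2):
            parent_field = "father_id" if f1.sex == "male" else "mother_id"
            kwargs = {parent_field: f1.id}
            individuals.append(
                Individual(f"{trio}_F2_{j}", "female", generation="F2",
                           mean_depth=spec.mean_depth, **kwargs)
            )
            q_true[(trio, j)] = rng_ages.uniform(*spec.q_range)

        # --- true DNMs ---------------------------------------------------
        lam_m = spec.beta0_m + spec.beta1_m * father_age
        lam_f = spec.beta0_f + spec.beta1_f * mother_age
        n_pat = rng_counts.poisson(lam_m)
        n_mat = rng_counts.poisson(lam_f)
        n_true = n_pat + n_mat
        origin = np.array(["paternal"] * n_pat + ["maternal"] * n_mat)
        rng_counts.shuffle(origin)

        deleted = rng_counts.random(n_true) < spec.fnr_true
        n_kept = int((~deleted).sum())

        # doublet clusters among kept true DNMs (pairs share a transmission fate)
        n_pairs = int(n_kept * spec.doublet_fraction / 2)

        # false positives: realized singlet contamination equals fdr_true
        n_kept_singlets = n_kept - 2 * n_pairs
        n_fp = round(spec.fdr_true / (1 - spec.fdr_true) * n_kept_singlets) \
            if spec.fdr_true < 1 else 0
        # artifact clusters of size 3 (removed by the cluster filter)
        n_triplets = rng_counts.poisson(spec.triplet_fp_rate)

        n_rows = n_kept + n_fp + 3 * n_triplets
        chrom, pos = _draw_positions(n_rows, spec, rng_pos)
        # co-locate doublet partners and triplet members
        kept_idx = np.arange(n_kept)
        for k in range(n_pairs):
            a, b = kept_idx[2 * k], kept_idx[2 * k + 1]
            chrom[b] = chrom[a]
            pos[b] = min(pos[a] + int(rng_pos.integers(1, 100)),
                         spec.chrom_sizes[chrom[a]])
        # a 2-DNM cluster is one mutational event: shared parent of origin
        for t in range(n_triplets):
            base = n_kept + n_fp + 3 * t
            for off in (1, 2):
                chrom[base + off] = chrom[base]
                pos[base + off] = min(pos[base] + off * int(rng_pos.integers(1, 50)),
                                      spec.chrom_sizes[chrom[base]])

        is_true = np.zeros(n_rows, dtype=bool)
        is_true[:n_kept] = True
        row_origin = np.full(n_rows, "NA", dtype=object)
        row_origin[:n_kept] = origin[~deleted]
        for k in range(n_pairs):
            row_origin[2 * k + 1] = row_origin[2 * k]
        pair_id = np.full(n_rows, -1)
        pair_id[: 2 * n_pairs] = np.repeat(np.arange(n_pairs), 2)

        # --- F2 observation (marginal probability q per pair) -------------
        f2_obs = np.zeros((n_rows, m_f2), dtype=bool)
        for j in range(m_f2):
            q = q_true[(trio, j)]
            draw = rng_obs.random(n_rows) < q
            draw[~is_true] = False
            # doublet partners co-transmit: second member copies the first
            for k in range(n_pairs):
                draw[2 * k + 1] = draw[2 * k]
            f2_obs[:, j] = draw

        # --- phase evidence ----------------------------------------------
        readbacked = np.full(n_rows, "NA", dtype=object)
        has_rb = rng_obs.random(n_rows) < spec.p_readbacked
        for idx in np.flatnonzero(has_rb):
            if is_true[idx]:
                readbacked[idx] = row_origin[idx]
            else:
                readbacked[idx] = "paternal" if rng_obs.random() < 0.5 else "maternal"
        transmission = np.full(n_rows, "NA", dtype=object)
        observed_any = f2_obs.any(axis=1)
        has_tp = observed_any & (rng_obs.random(n_rows) < spec.p_transmission_phase)
        transmission[has_tp] = row_origin[has_tp]

        metrics = _passing_metrics(n_rows, spec.mean_depth, rng_metrics)
        muts = _draw_mutation_types(n_rows, spec.mutation_type_probs, rng_types)
        table = pd.DataFrame(
            {
                "trio_id": trio,
                "chrom": chrom,
                "pos": pos,
                "ref": muts["ref"],
                "alt": muts["alt"],
            }
        )
        table = pd.concat([table, metrics], axis=1)
        table["ctx5"] = muts["ctx5"]
        table["ctx3"] = muts["ctx3"]
        table["f2_observed"] = [
            ",".join("1" if v else "0" for v in row) for row in f2_obs
        ]
        table["readbacked_phase"] = readbacked
        table["transmission_phase"] = transmission
        candidate_rows.append(table[CANDIDATE_COLUMNS])

        truth_rows.append(
            pd.DataFrame(
                {
                    "trio_id": trio,
                    "chrom": chrom,
                    "pos": pos,
                    "is_true": is_true,
                    "parent_of_origin": row_origin,
                    "true_type": muts["true_type"],
                    "doublet_pair": pair_id,
                    "n_true_total": n_true,
                    "n_deleted_fnr": int(deleted.sum()),
                }
            )
        )

        # --- companion simulation tables ----------------------------------
        for j in range(m_f2):
            n_eligible = spec.n_sim_transmission
            n_observed = int(rng_sim.binomial(n_eligible, q_true[(trio, j)]))
            trans_rows.append(
                {
                    "trio_id": trio,
                    "f2_index": j,
                    "n_eligible": n_eligible,
                    "n_observed": n_observed,
                }
            )

    pedigree = Pedigree(individuals)
    candidates = pd.concat(candidate_rows, ignore_index=True)
    truth = pd.concat(truth_rows, ignore_index=True)
    # one batched draw covering every trio's simulated-DNM table
    trios_sorted = sorted(truth["trio_id"].unique())
    filter_sim = simulate_filter_table(
        spec, spec.n_sim_fnr * len(trios_sorted), rng_sim
    )
    filter_sim["trio_id"] = np.repeat(trios_sorted, spec.n_sim_fnr)
    return SimulatedCohort(
        spec=spec,
        pedigree=pedigree,
        candidates=candidates,
        truth=truth,
        transmission_sim=pd.DataFrame(trans_rows),
        filter_sim=filter_sim,
        q_true=q_true,
        ages=pd.DataFrame(age_rows),
    )


_DEFECTS = ["low_gq", "low_ad", "skewed_ab", "low_qual", "parent_alt"]


def simulate_filter_table(
    spec: CohortSpec,
    n_sites: int,
    rng: np.random.Generator | None = None,
    trio_id: str = "",
    fail_fraction: float | None = None,
) -> pd.DataFrame:
    """Simulated-DNM table mimicking the pedigree-simulation FNR input.

    Each row carries full genotype metrics and a recorded pass/fail ground
    truth (``survived``) obtained by running the actual filter battery.  A
    fraction ``fail_fraction`` (default: the spec's fnr_true) of rows receives
    one injected defect that places a metric in a rejection region; the
    remainder draw passing metrics.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    fail_fraction = spec.fnr_true if fail_fraction is None else fail_fraction
    cols = _passing_metric_arrays(n_sites, spec.mean_depth, rng)
    chrom, pos = _draw_positions(n_sites, spec, rng)
    defect = np.full(n_sites, "none", dtype=object)
    fail = rng.random(n_sites) < fail_fraction
    kinds = rng.choice(len(_DEFECTS), size=n_sites)
    for k, kind in enumerate(_DEFECTS):
        mask = fail & (kinds == k)
        n = int(mask.sum())
        if not n:
            continue
        defect[mask] = kind
        if kind == "low_gq":
            cols["child_gq"][mask] = rng.integers(0, 40, size=n)
        elif kind == "low_ad":
            cols["child_ad_alt"][mask] = rng.integers(0, 3, size=n)
        elif kind == "skewed_ab":
            cols["child_dp"][mask] = np.maximum(cols["child_dp"][mask], 25)
            cols["child_ad_alt"][mask] = cols["child_dp"][mask] - 2
        elif kind == "low_qual":
            cols["qual"][mask] = rng.uniform(0, 99, size=n)
        elif kind == "parent_alt":
            cols["father_ad_alt"][mask] = rng.integers(2, 6, size=n)
            cols["mother_ad_alt"][mask] = rng.integers(2, 6, size=n)
    cols["child_ad_ref"] = cols["child_dp"] - cols["child_ad_alt"]
    table = pd.DataFrame(
        {
            "trio_id": np.full(n_sites, trio_id or "sim"),
            "chrom": chrom,
            "pos": pos,
            "ref": np.full(n_sites, "C"),
            "alt": np.full(n_sites, "T"),
            **cols,
            "ctx5": np.full(n_sites, "A"),
            "ctx3": np.full(n_sites, "A"),
            "f2_observed": np.full(n_sites, ""),
            "readbacked_phase": np.full(n_sites, "NA"),
            "transmission_phase": np.full(n_sites, "NA"),
            "defect": defect,
        }
    )
    passed, _ = apply_site_filters(table, FilterConfig())
    table["survived"] = table.index.isin(passed.index)
    return table
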