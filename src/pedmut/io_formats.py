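"""Readers, writers and validated containers for the pipeline's external artifacts.

All coordinates follow the conventions of the file format they came from:
interval sets are 0-based half-open (BED dialect), variant positions are
1-based (VCF dialect).  Conversion between the two is centralized here.
Missing values are written as the explicit sentinel ``NA``, never left blank.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pyranges as pr

NA = "NA"

PEDIGREE_COLUMNS = [
    "id",
    "sex",
    "father_id",
    "mother_id",
    "generation",
    "mean_depth",
    "age_father_at_conception",
    "age_mother_at_conception",
]

GENERATION_ORDER = {"P0": 0, "F1": 1, "F2": 2}


class PedigreeError(ValueError):
    """Raised when a pedigree file violates its invariants."""


@dataclass
class Individual:
    id: str
    sex: str  # "male" | "female"
    father_id: str | None = None
    mother_id: str | None = None
    generation: str = "F1"  # "P0" | "F1" | "F2"
    mean_depth: float | None = None
    age_father_at_conception: float | None = None
    age_mother_at_conception: float | None = None


@dataclass
class Pedigree:
    """A 3-generation pedigree: P0 grandparents, focal F1 children, F2 grandchildren."""

    individuals: list[Individual]

    def __post_init__(self) -> None:
        ids = [ind.id for ind in self.individuals]
        if not ids:
            raise PedigreeError("no individuals")
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise PedigreeError(f"duplicate id(s): {sorted(dupes)}")
        self._by_id = {ind.id: ind for ind in self.individuals}
        for ind in self.individuals:
            for parent_id in (ind.father_id, ind.mother_id):
                if parent_id is None:
                    continue
                parent = self._by_id.get(parent_id)
                if parent is None:
                    continue  # unknown parents are recorded as missing, not errors
                if GENERATION_ORDER[parent.generation] >= GENERATION_ORDER[ind.generation]:
                    raise PedigreeError(
                        f"child {ind.id} ({ind.generation}) does not postdate "
                        f"parent {parent.id} ({parent.generation})"
                    )
            for age in (ind.age_father_at_conception, ind.age_mother_at_conception):
                if age is not None and age < 0:
                    raise PedigreeError(f"negative parental age for {ind.id}")

    def __getitem__(self, ind_id: str) -> Individual:
        return self._by_id[ind_id]

    def __contains__(self, ind_id: str) -> bool:
        return ind_id in self._by_id

    @property
    def focal_f1(self) -> list[Individual]:
        """F1 individuals with both parents present in the pedigree (the trios)."""
        return [
            ind
            for ind in self.individuals
            if ind.generation == "F1"
            and ind.father_id in self._by_id
            and ind.mother_id in self._by_id
        ]

    def f2_children(self, f1_id: str) -> list[Individual]:
        return [
            ind
            for ind in self.individuals
            if ind.generation == "F2" and f1_id in (ind.father_id, ind.mother_id)
        ]


def _parse_optional_float(token: str) -> float | None:
    return None if token == NA else float(token)


def read_pedigree(path) -> Pedigree:
    """Read a tab-separated pedigree table (header required, ``NA`` for missing)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in PEDIGREE_COLUMNS if c not in df.columns]
    if missing:
        raise PedigreeError(f"missing columns: {missing}")
    if df.empty:
        raise PedigreeError("no individuals")
    individuals = []
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            individuals.append(
                Individual(
                    id=row.id,
                    sex=row.sex,
                    father_id=None if row.father_id == NA else row.father_id,
                    mother_id=None if row.mother_id == NA else row.mother_id,
                    generation=row.generation,
                    mean_depth=_parse_optional_float(row.mean_depth),
                    age_father_at_conception=_parse_optional_float(
                        row.age_father_at_conception
                    ),
                    age_mother_at_conception=_parse_optional_float(
                        row.age_mother_at_conception
                    ),
                )
            )
        except (ValueError, KeyError) as exc:
            raise PedigreeError(f"line {line_no}: {exc}") from exc
    try:
        return Pedigree(individuals)
    except PedigreeError as exc:
        raise PedigreeError(str(exc)) from exc


def write_pedigree(pedigree: Pedigree, path) -> None:
    rows = []
    for ind in pedigree.individuals:
        d = dataclasses.asdict(ind)
        rows.append({k: NA if d[k] is None else d[k] for k in PEDIGREE_COLUMNS})
    pd.DataFrame(rows, columns=PEDIGREE_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Interval sets (BED dialect, 0-based half-open)
# ---------------------------------------------------------------------------


class IntervalSet:
    """A normalized (sorted, merged) set of genomic intervals.

    Backed by pyranges; all set operations return new normalized sets so the
    half-open interval algebra behaves like set algebra on base positions.
    """

    def __init__(self, intervals: Iterable[tuple[str, int, int]] = ()):
        records = list(intervals)
        for chrom, start, end in records:
            if start >= end:
                raise ValueError(f"start >= end in interval ({chrom}, {start}, {end})")
            if start < 0:
                raise ValueError(f"negative start in interval ({chrom}, {start}, {end})")
        if records:
            df = pd.DataFrame(records, columns=["Chromosome", "Start", "End"])
            self._pr = pr.PyRanges(df).merge()
        else:
            self._pr = pr.PyRanges()

    @classmethod
    def _from_pyranges(cls, ranges: pr.PyRanges) -> "IntervalSet":
        obj = cls()
        obj._pr = ranges.merge() if len(ranges) else pr.PyRanges()
        return obj

    def to_tuples(self) -> list[tuple[str, int, int]]:
        if not len(self._pr):
            return []
        df = self._pr.df.sort_values(["Chromosome", "Start"])
        return [
            (str(c), int(s), int(e))
            for c, s, e in zip(df.Chromosome, df.Start, df.End)
        ]

    @property
    def total_bp(self) -> int:
        if not len(self._pr):
            return 0
        return int(self._pr.lengths().sum())

    def __len__(self) -> int:
        return len(self._pr)

    def __eq__(self, other) -> bool:
        return isinstance(other, IntervalSet) and self.to_tuples() == other.to_tuples()

    def union(self, other: "IntervalSet") -> "IntervalSet":
        return IntervalSet(self.to_tuples() + other.to_tuples())

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        if not len(self._pr) or not len(other._pr):
            return IntervalSet()
        return IntervalSet._from_pyranges(self._pr.intersect(other._pr))

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        if not len(self._pr):
            return IntervalSet()
        if not len(other._pr):
            return IntervalSet(self.to_tuples())
        return IntervalSet._from_pyranges(self._pr.subtract(other._pr))

    def contains(self, chrom: str, pos0: int) -> bool:
        """Membership of a single 0-based position."""
        return any(
            c == chrom and s <= pos0 < e for c, s, e in self.to_tuples()
        )

    def contains_variant(self, chrom: str, pos1: int) -> bool:
        """Membership of a 1-based variant position (VCF dialect)."""
        return self.contains(chrom, pos1 - 1)


def read_intervals(path) -> IntervalSet:
    """Read a BED file (0-based half-open) into a normalized IntervalSet."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=[0, 1, 2],
        names=["chrom", "start", "end"],
        dtype={"chrom": str},
    )
    return IntervalSet(
        (str(c), int(s), int(e)) for c, s, e in zip(df.chrom, df.start, df.end)
    )


def write_intervals(intervals: IntervalSet, path) -> None:
    pd.DataFrame(intervals.to_tuples(), columns=["chrom", "start", "end"]).to_csv(
        path, sep="\t", header=False, index=False
    )


# ---------------------------------------------------------------------------
# Genetic maps
# ---------------------------------------------------------------------------


@dataclass
class GeneticMap:
    """Piecewise-linear physical position (bp) -> genetic position (cM), per chromosome."""

    chrom_maps: dict[str, tuple[np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        for chrom, (pos, cm) in self.chrom_maps.items():
            pos = np.asarray(pos, dtype=float)
            cm = np.asarray(cm, dtype=float)
            if len(pos) != len(cm) or len(pos) < 2:
                raise ValueError(f"{chrom}: need >= 2 (position, cM) points")
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"{chrom}: positions must be strictly increasing")
            if np.any(np.diff(cm) < 0):
                raise ValueError(f"{chrom}: cM must be non-decreasing")
            self.chrom_maps[chrom] = (pos, cm)

    def cm_at(self, chrom: str, positions) -> np.ndarray:
        """Interpolate cM at 1-based positions; queries beyond the map clamp to its ends."""
        pos, cm = self.chrom_maps[chrom]
        return np.interp(np.asarray(positions, dtype=float), pos, cm)

    def chrom_length_cm(self, chrom: str) -> float:
        _, cm = self.chrom_maps[chrom]
        return float(cm[-1] - cm[0])

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self.chrom_maps)


def read_genetic_map(path) -> GeneticMap:
    """Read a tab-separated map with columns chrom, position, cM."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "position", "cM"}
    if not required.issubset(df.columns):
        raise ValueError(f"genetic map needs columns {sorted(required)}")
    chrom_maps = {}
    for chrom, sub in df.groupby("chrom", sort=True):
        sub = sub.sort_values("position")
        chrom_maps[str(chrom)] = (
            sub["position"].to_numpy(float),
            sub["cM"].to_numpy(float),
        )
    return GeneticMap(chrom_maps)


def write_genetic_map(gmap: GeneticMap, path) -> None:
    rows = []
    for chrom in gmap.chromosomes:
        pos, cm = gmap.chrom_maps[chrom]
        rows.extend({"chrom": chrom, "position": p, "cM": c} for p, c in zip(pos, cm))
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def renormalize_rho_map(
    positions: Sequence[float], rho: Sequence[float], target_length_cm: float
) -> GeneticMap:
    """Convert a population-scaled recombination map (rho between adjacent markers)
    to a cM map for one chromosome.

    rho[i] is the rate between positions[i] and positions[i+1].  Each rate is
    weighted by the physical span it covers, and the cumulative map is rescaled
    so the chromosome's total genetic length equals ``target_length_cm``.
    """
    positions = np.asarray(positions, dtype=float)
    rho = np.asarray(rho, dtype=float)
    if len(rho) != len(positions) - 1:
        raise ValueError("need one rho value per adjacent marker pair")
    if np.any(rho < 0):
        raise ValueError("rho must be nonnegative")
    weighted = rho * np.diff(positions)
    cumulative = np.concatenate([[0.0], np.cumsum(weighted)])
    total = cumulative[-1]
    if total <= 0:
        raise ValueError("map has zero total recombination")
    cm = cumulative * (target_length_cm / total)
    return GeneticMap({"renormalized": (positions, cm)})


# ---------------------------------------------------------------------------
# Candidate-DNM tables
# ---------------------------------------------------------------------------

#: Column contract for candidate Mendelian-violation site tables.  Positions are
#: 1-based.  ``f2_observed`` is a comma-separated list of 0/1 flags (one per F2,
#: empty string when no F2 exists).  Phase evidence columns use the labels
#: paternal/maternal/ambiguous/conflict or NA.
CANDIDATE_COLUMNS = [
    "trio_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "qual",
    "child_gt",
    "child_ad_ref",
    "child_ad_alt",
    "child_dp",
    "child_gq",
    "father_gt",
    "father_ad_ref",
    "father_ad_alt",
    "father_dp",
    "father_gq",
    "mother_gt",
    "mother_ad_ref",
    "mother_ad_alt",
    "mother_dp",
    "mother_gq",
    "QD",
    "FS",
    "MQ",
    "MQRankSum",
    "ReadPosRankSum",
    "SOR",
    "known_variant",
    "other_family_alt",
    "ctx5",
    "ctx3",
    "f2_observed",
    "readbacked_phase",
    "transmission_phase",
]

_HARD_FILTER_INFO_KEYS = ["QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum", "SOR"]


_NUMERIC_CANDIDATE_COLUMNS = [
    "pos", "qual",
    "child_ad_ref", "child_ad_alt", "child_dp", "child_gq",
    "father_ad_ref", "father_ad_alt", "father_dp", "father_gq",
    "mother_ad_ref", "mother_ad_alt", "mother_dp", "mother_gq",
    "QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum", "SOR",
]
_BOOL_CANDIDATE_COLUMNS = ["known_variant", "other_family_alt"]


def read_candidates(path) -> pd.DataFrame:
    """Read a candidate table: numeric metrics parse the ``NA`` sentinel as
    missing; categorical string columns (contexts, phase evidence) keep it."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in CANDIDATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"candidate table missing columns: {missing}")
    for col in _NUMERIC_CANDIDATE_COLUMNS:
        df[col] = pd.to_numeric(df[col].replace(NA, None), errors="raise")
    for col in _BOOL_CANDIDATE_COLUMNS:
        df[col] = df[col].map({"True": True, "False": False, "1": True, "0": False})
    df["pos"] = df["pos"].astype(int)
    bad = df["ref"] == df["alt"]
    if bad.any():
        raise ValueError(f"ref == alt at rows {list(df.index[bad])}")
    return df


def write_candidates(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=NA)


def read_candidates_vcf(path, trio_id: str, child: str, father: str, mother: str) -> pd.DataFrame:
    """Import candidate sites from a VCF with GT/AD/DP/GQ FORMAT fields and the
    GATK hard-filter INFO keys.  Context and phase-evidence columns are filled
    with missing values; they come from separate tables.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = {name: i for i, name in enumerate(vcf.samples)}
    for name in (child, father, mother):
        if name not in samples:
            raise ValueError(f"sample {name} not in VCF")
    rows = []
    for variant in vcf:
        if len(variant.ALT) != 1:
            continue
        row = {
            "trio_id": trio_id,
            "chrom": variant.CHROM,
            "pos": variant.POS,
            "ref": variant.REF,
            "alt": variant.ALT[0],
            "qual": variant.QUAL,
        }
        ad = variant.format("AD")
        dp = variant.format("DP")
        gq = variant.format("GQ")
        gts = variant.gt_types  # 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        gt_label = {0: "0/0", 1: "0/1", 2: "1/1", 3: "./."}
        for role, name in (("child", child), ("father", father), ("mother", mother)):
            i = samples[name]
            row[f"{role}_gt"] = gt_label[int(gts[i])]
            row[f"{role}_ad_ref"] = int(ad[i][0])
            row[f"{role}_ad_alt"] = int(ad[i][1])
            row[f"{role}_dp"] = int(dp[i][0]) if dp.ndim > 1 else int(dp[i])
            row[f"{role}_gq"] = int(gq[i][0]) if gq.ndim > 1 else int(gq[i])
        for key in _HARD_FILTER_INFO_KEYS:
            row[key] = variant.INFO.get(key)
        row.update(
            known_variant=False,
            other_family_alt=False,
            ctx5=NA,
            ctx3=NA,
            f2_observed="",
            readbacked_phase=NA,
            transmission_phase=NA,
        )
        rows.append(row)
    return pd.DataFrame(rows, columns=CANDIDATE_COLUMNS)
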