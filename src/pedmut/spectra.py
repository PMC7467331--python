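"""Mutation spectrum classification and comparison.

Single-base substitutions are collapsed with their reverse complements onto a
pyrimidine (C or T) reference strand and classified into 7 disjoint types:
C>A, C>G, T>A, T>C, T>G, CpG>TpG and CpH>TpH — C>T transitions split by
whether the 3' neighbour on the collapsed strand is a G (a CpG dinucleotide,
where spontaneous deamination of methylated cytosine drives the high
transition rate) or not (H = A, C or T).

A coarser strong/weak scheme labels substitutions by whether they swap
strong (S: G/C) and weak (W: A/T) base pairs — the axes along which GC-biased
gene conversion distorts fixation — with S>W additionally split by CpG
status, for 5 types.

Two spectra are compared by the forward variable selection procedure:
repeatedly test each remaining type against the rest in a 2x2 chi-square,
remove the most significant type, and stop once nothing remains significant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GeneticMap
from .rates_regression import block_bootstrap

MUTATION_TYPES_7 = ["C>A", "C>G", "T>A", "T>C", "T>G", "CpG>TpG", "CpH>TpH"]
MUTATION_TYPES_SW = ["S>S", "W>W", "W>S", "S>W CpG", "S>W non-CpG"]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_STRONG = {"C", "G"}


def _check_bases(*bases: str) -> None:
    for b in bases:
        if b not in _COMPLEMENT:
            raise ValueError(f"base {b!r} is not one of A/C/G/T")


def _collapse(ref: str, alt: str, base5: str, base3: str) -> tuple[str, str, str, str]:
    """Reverse-complement purine-reference substitutions onto the pyrimidine
    strand, swapping and complementing the context accordingly."""
    if ref in ("A", "G"):
        return (
            _COMPLEMENT[ref],
            _COMPLEMENT[alt],
            _COMPLEMENT[base3],
            _COMPLEMENT[base5],
        )
    return ref, alt, base5, base3


def classify7(ref: str, alt: str, base5: str, base3: str) -> str:
    """Classify one substitution with its 5'/3' context into the 7-type scheme."""
    _check_bases(ref, alt, base5, base3)
    if ref == alt:
        raise ValueError("ref == alt is not a substitution")
    ref, alt, base5, base3 = _collapse(ref, alt, base5, base3)
    if ref == "C" and alt == "T":
        return "CpG>TpG" if base3 == "G" else "CpH>TpH"
    return f"{ref}>{alt}"


def classifySW(ref: str, alt: str, base5: str, base3: str) -> str:
    """Classify one substitution into the 5-type strong/weak scheme.

    A site is CpG when the reference C is followed by G (equivalently, a
    reference G preceded by C on the other strand).
    """
    _check_bases(ref, alt, base5, base3)
    if ref == alt:
        raise ValueError("ref == alt is not a substitution")
    s_ref = ref in _STRONG
    s_alt = alt in _STRONG
    if s_ref and s_alt:
        return "S>S"
    if not s_ref and not s_alt:
        return "W>W"
    if not s_ref:
        return "W>S"
    cpg = (ref == "C" and base3 == "G") or (ref == "G" and base5 == "C")
    return "S>W CpG" if cpg else "S>W non-CpG"


def classify_table(mutations: pd.DataFrame, scheme: str = "7") -> pd.Series:
    """Vector classification of a mutation table with ref/alt/ctx5/ctx3 columns."""
    fn = classify7 if scheme == "7" else classifySW
    return mutations.apply(
        lambda row: fn(row["ref"], row["alt"], row["ctx5"], row["ctx3"]), axis=1
    )


def spectrum(
    mutations: pd.DataFrame,
    genetic_map: GeneticMap | None = None,
    block_cm: float = 50.0,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """7-type spectrum (proportions summing to 1) with optional bootstrap CIs.

    With a genetic map the CIs come from resampling 50 cM blocks; without one
    only the point proportions are returned.
    """
    if mutations.empty:
        raise ValueError("need at least one classifiable mutation")
    labels = classify_table(mutations, "7")
    props = (
        labels.value_counts(normalize=True)
        .reindex(MUTATION_TYPES_7)
        .fillna(0.0)
    )
    out = pd.DataFrame({"proportion": props})
    if genetic_map is not None:
        annotated = mutations.assign(_type=labels.to_numpy())
        los, his = [], []
        for mtype in MUTATION_TYPES_7:
            (lo, hi), _ = block_bootstrap(
                annotated,
                genetic_map,
                lambda df, t=mtype: (df["_type"] == t).mean(),
                block_cm=block_cm,
                n_boot=n_boot,
                rng=rng,
            )
            los.append(lo)
            his.append(hi)
        out["ci_low"] = los
        out["ci_high"] = his
    return out


def _two_by_two_p(a_in: int, a_out: int, b_in: int, b_out: int) -> tuple[float, bool]:
    """Chi-square p (no continuity correction) for one type vs the rest;
    falls back to Fisher's exact test on a degenerate zero-margin table."""
    table = np.array([[a_in, a_out], [b_in, b_out]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return float(stats.fisher_exact(table)[1]), True
    _, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(p), False


def forward_selection_compare(
    counts_a,
    counts_b,
    types: list[str] | None = None,
    threshold: float = 0.05,
) -> pd.DataFrame:
    """Rank the mutation types that differ between two spectra.

    At each iteration every remaining type is tested (type vs all other
    remaining types, dataset A vs B) with a 2x2 chi-square; the most
    significant type is removed and its p-value at removal recorded.  The
    procedure stops when all remaining p-values exceed ``threshold`` or one
    type remains.  Returns the removal log (type, p_at_removal, iteration,
    exact_fallback); an empty frame means no detectable difference.
    """
    types = list(MUTATION_TYPES_7 if types is None else types)
    counts_a = np.asarray(counts_a, dtype=float)
    counts_b = np.asarray(counts_b, dtype=float)
    if len(types) != counts_a.size or counts_a.size != counts_b.size:
        raise ValueError("counts must align with the type labels")
    if (counts_a > 0).sum() < 2 and (counts_b > 0).sum() < 2:
        raise ValueError("need counts in at least 2 types")
    remaining = list(range(len(types)))
    log = []
    iteration = 0
    while len(remaining) > 1:
        tot_a = counts_a[remaining].sum()
        tot_b = counts_b[remaining].sum()
        results = []
        for i in remaining:
            p, exact = _two_by_two_p(
                int(counts_a[i]),
                int(tot_a - counts_a[i]),
                int(counts_b[i]),
                int(tot_b - counts_b[i]),
            )
            results.append((p, i, exact))
        results.sort()
        best_p, best_i, best_exact = results[0]
        if best_p > threshold:
            break
        log.append(
            {
                "type": types[best_i],
                "p_at_removal": best_p,
                "iteration": iteration,
                "exact_fallback": best_exact,
            }
        )
        remaining.remove(best_i)
        iteration += 1
    return pd.DataFrame(log, columns=["type", "p_at_removal", "iteration", "exact_fallback"])
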