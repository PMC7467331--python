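"""Parent-of-origin assignment of DNMs from two independent evidence sources.

Read-backed phasing links the DNM to nearby informative SNPs on the same
sequencing reads; transmission phasing follows the DNM into the third
generation and reads off the grandparental background of the co-transmitted
haplotype.  This module implements only the consensus layer: each source
produces a paternal/maternal call (or none), and the two are combined under
explicit conflict rules.  Haplotype estimation itself (read-backed phasing,
pedigree HMMs) happens upstream; its outputs are this module's inputs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

PATERNAL = "paternal"
MATERNAL = "maternal"
AMBIGUOUS = "ambiguous"
NONE = "none"
CONFLICT = "conflict"
UNPHASED = "unphased"
DISCARDED = "discarded"


@dataclass
class PhaseCall:
    """Phase evidence and consensus for one DNM."""

    dnm_id: str
    readbacked: str = NONE  # paternal | maternal | ambiguous | none
    transmission: list[str] = field(default_factory=list)  # per-F2 calls
    partial_linkage: bool = False
    consensus: str = UNPHASED


def readbacked_assign(informative_snp_origins: list[str]) -> str:
    """Assign a haplotype's parental background from its informative SNPs.

    All informative SNPs agreeing -> that parent; any disagreement between
    maternally and paternally inherited SNPs -> ambiguous; no informative
    SNPs -> none.
    """
    origins = set(informative_snp_origins)
    if not origins:
        return NONE
    bad = origins - {PATERNAL, MATERNAL}
    if bad:
        raise ValueError(f"unknown origins: {sorted(bad)}")
    if len(origins) == 1:
        return next(iter(origins))
    return AMBIGUOUS


def transmission_assign(
    observed_in_f2: bool,
    haplotype_background: str,
    recomb_prob_left: float | None = None,
    recomb_prob_right: float | None = None,
) -> str:
    """Phase a transmitted DNM from the background of the co-inherited haplotype.

    The DNM takes the background of the flanking informative SNPs, unless a
    recombination event with probability > 50% lies before the first
    informative SNP on BOTH sides of the DNM, in which case the call flips
    (a double crossover moved the DNM off the tagged background).
    """
    if not observed_in_f2:
        return NONE
    if haplotype_background not in (PATERNAL, MATERNAL):
        return NONE
    flip = (
        recomb_prob_left is not None
        and recomb_prob_right is not None
        and recomb_prob_left > 0.5
        and recomb_prob_right > 0.5
    )
    if flip:
        return MATERNAL if haplotype_background == PATERNAL else PATERNAL
    return haplotype_background


def consensus(call: PhaseCall) -> str:
    """Combine read-backed and transmission evidence into one consensus label.

    Rules, in order:
    * transmission calls from multiple F2s that disagree: resolved by the
      read-backed call when one exists, otherwise discarded;
    * partial-linkage DNMs (observed in one of two F2s sharing the haplotype):
      discarded if discordant with read-backed evidence, else assigned the
      transmitted haplotype;
    * read-backed vs transmission disagreement: discarded;
    * a single source (ambiguous read-backed evidence never counts): its call;
    * no evidence: unphased.

    The result is deterministic and independent of evidence-list order.
    """
    rb = call.readbacked if call.readbacked in (PATERNAL, MATERNAL) else None
    trans_calls = [t for t in call.transmission if t in (PATERNAL, MATERNAL)]
    trans_set = set(trans_calls)

    if len(trans_set) > 1:  # two F2s disagree
        result = rb if rb is not None else DISCARDED
    elif len(trans_set) == 1:
        trans = next(iter(trans_set))
        if rb is None:
            result = trans
        elif rb == trans:
            result = trans
        else:
            result = DISCARDED
    else:
        result = rb if rb is not None else UNPHASED

    call.consensus = result
    return result


def consensus_table(calls: list[PhaseCall]) -> list[PhaseCall]:
    for call in calls:
        consensus(call)
    return calls


def phased_fraction(
    calls: list[PhaseCall], restrict_to_transmitted: bool = False
) -> dict[str, float]:
    """Counts of paternal/maternal consensus calls and the paternal fraction.

    With ``restrict_to_transmitted`` only DNMs observed in at least one F2 are
    counted (the low-FDR subset used for the male-bias estimate).
    """
    selected = []
    for call in calls:
        if restrict_to_transmitted and not any(
            t in (PATERNAL, MATERNAL) for t in call.transmission
        ):
            continue
        if call.consensus in (PATERNAL, MATERNAL):
            selected.append(call.consensus)
    if not selected:
        raise ValueError("no phased DNMs after restriction")
    counts = Counter(selected)
    n_pat = counts.get(PATERNAL, 0)
    n_mat = counts.get(MATERNAL, 0)
    return {
        "n_paternal": n_pat,
        "n_maternal": n_mat,
        "fraction_paternal": n_pat / (n_pat + n_mat),
    }
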