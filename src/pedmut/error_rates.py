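"""Per-trio error rates of the DNM calling pipeline.

Two error rates enter every downstream count adjustment:

* the false negative rate (FNR), the fraction of genuine DNMs removed by the
  filter battery, estimated by running simulated Mendelian violations through
  the same filters;
* the false discovery rate (FDR), the fraction of called DNMs that are
  spurious, estimated from transmission to the third generation.  A genuine
  DNM in an F1 is observed in a given F2 with probability q (close to, but not
  exactly, 1/2: transmission is Mendelian but the calling pipeline has
  imperfect and genotype-sharing-dependent power); a spurious call is assumed
  never observed in an F2.  The number of true DNMs w is then estimated by
  integer maximum likelihood from the observed transmission counts, and
  FDR = 1 - w_hat / y where y is the number of called DNMs.

Singlet DNMs get a per-trio FDR; doublets (members of 2-DNM clusters) are so
rare that a single pooled FDR is estimated across trios, with a doublet
counted as observed only when both members transmit.  Trios without an F2 get
an FDR imputed from the regression of known FDRs on F1 sequencing depth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

#: Pedigree-loop correction for sires whose simulated DNMs can also transmit
#: through the masked parent: Mendelian transmission probability 0.5 over the
#: realized simulated-site transmission probability 0.25 + 0.375 = 0.625.
LOOP_CORRECTION = 0.5 / 0.625


@dataclass
class TransmissionModel:
    """Observation model for transmission of one F1's DNMs to its F2 offspring."""

    trio_id: str
    q: tuple[float, ...]  # per-F2 observation probabilities, length m in {0, 1, 2}

    def __post_init__(self) -> None:
        if len(self.q) > 2:
            raise ValueError("at most 2 F2 offspring are modelled")
        for qj in self.q:
            if not 0 < qj < 1:
                raise ValueError("q must lie strictly in (0, 1)")

    @property
    def m(self) -> int:
        return len(self.q)


@dataclass
class FdrEstimate:
    trio_id: str
    y: int
    w_hat: int
    fdr: float
    loglik: float
    ci: tuple[float, float] | None = None
    imputed: bool = False


@dataclass
class FnrEstimate:
    trio_id: str
    n_simulated: int
    n_failed: int
    fnr: float
    ci: tuple[float, float]


@dataclass
class ErrorRateSet:
    """Error rates feeding the adjusted-count formula."""

    singlet_fdr: dict[str, FdrEstimate] = field(default_factory=dict)
    doublet_fdr: FdrEstimate | None = None
    fnr: dict[str, FnrEstimate] = field(default_factory=dict)


def estimate_q(
    n_observed: int, n_eligible: int, loop: bool = False
) -> float:
    """Per F1-F2 pair observation probability from simulated transmissions.

    q~ is the fraction of simulated, filter-passing DNMs observed in the F2;
    for pedigree-loop sires it is multiplied by 0.5/0.625 = 0.8.
    """
    if n_eligible < 1:
        raise ValueError("no eligible simulated transmissions")
    q = n_observed / n_eligible
    if loop:
        q *= LOOP_CORRECTION
    if q >= 1.0:
        warnings.warn("degenerate observation probability q = 1", stacklevel=2)
    return q


def _singlet_loglik(w: np.ndarray, z, model: TransmissionModel) -> np.ndarray:
    """Log-likelihood of transmission counts given w true DNMs.

    m=1: z observed ~ Binomial(w, q1).
    m=2: counts (z_B, z_C, z_D) for observed-in-first-only / second-only /
    both ~ Multinomial(w, q_vec); the unobserved-in-both category count is
    w - z_B - z_C - z_D, computable because spurious DNMs never transmit.
    """
    if model.m == 1:
        return stats.binom.logpmf(int(z), w, model.q[0])
    q1, q2 = model.q
    z_b, z_c, z_d = (int(v) for v in z)
    z_a = w - z_b - z_c - z_d
    counts = np.stack(
        [z_a, np.full_like(w, z_b), np.full_like(w, z_c), np.full_like(w, z_d)],
        axis=-1,
    )
    probs = [(1 - q1) * (1 - q2), q1 * (1 - q2), (1 - q1) * q2, q1 * q2]
    return stats.multinomial.logpmf(counts, n=w, p=probs)


def fdr_singlet_mle(
    y: int, z, model: TransmissionModel, trio_id: str | None = None
) -> FdrEstimate:
    """Constrained integer ML estimate of the per-trio singlet FDR.

    The likelihood is maximized over the integer grid w in [z_total, y] by
    exhaustive evaluation; ties are broken toward the smaller w (the larger,
    more conservative FDR).  FDR = 1 - w_hat/y.
    """
    if model.m == 0:
        raise ValueError("trio has no F2; impute the FDR from coverage instead")
    z_total = int(z) if model.m == 1 else int(sum(z))
    if z_total > y:
        raise ValueError(f"observed transmissions ({z_total}) exceed singlets ({y})")
    if y == 0:
        return FdrEstimate(trio_id or model.trio_id, 0, 0, 0.0, 0.0)
    w_grid = np.arange(z_total, y + 1)
    ll = _singlet_loglik(w_grid, z, model)
    # smallest w within numerical tolerance of the maximum: exact likelihood
    # ties (e.g. z/q integer) resolve to the conservative, larger FDR
    w_hat = int(w_grid[np.flatnonzero(ll >= ll.max() - 1e-9)[0]])
    return FdrEstimate(
        trio_id=trio_id or model.trio_id,
        y=int(y),
        w_hat=w_hat,
        fdr=1.0 - w_hat / y,
        loglik=float(np.max(ll)),
    )


def fdr_doublet_pooled(
    y2_by_trio: dict[str, int], z2: int, q_bar: float
) -> FdrEstimate | None:
    """Pooled doublet FDR across trios.

    y2 counts doublet DNMs per trio; z2 counts doublets whose two members both
    transmitted; q_bar is the arithmetic mean of q over all F1-F2 pairs.
    Returns None (missing) when no doublets exist.
    """
    y_total = int(sum(y2_by_trio.values()))
    if y_total == 0:
        return None
    model = TransmissionModel(trio_id="pooled_doublets", q=(q_bar,))
    return fdr_doublet_from_counts(y_total, z2, model)


def fdr_doublet_from_counts(
    y_total: int, z2: int, model: TransmissionModel
) -> FdrEstimate:
    est = fdr_singlet_mle(y_total, z2, model, trio_id=model.trio_id)
    return est


def impute_fdr_from_coverage(
    known: list[tuple[float, float]], target_depths: list[float]
) -> list[float]:
    """Predict FDRs for trios lacking an F2 from the FDR-vs-coverage regression.

    Ordinary least squares of known (F1 mean depth, FDR) pairs; predictions
    are clamped to [0, 1].  With no depth variation the mean FDR is returned
    with a warning.
    """
    if len(known) < 2:
        raise ValueError("need at least 2 known (depth, FDR) pairs")
    depths = np.asarray([d for d, _ in known], dtype=float)
    fdrs = np.asarray([f for _, f in known], dtype=float)
    if np.ptp(depths) == 0:
        warnings.warn(
            "all depths identical; falling back to mean FDR", stacklevel=2
        )
        return [float(np.clip(fdrs.mean(), 0, 1))] * len(target_depths)
    slope, intercept = np.polyfit(depths, fdrs, 1)
    preds = intercept + slope * np.asarray(target_depths, dtype=float)
    return [float(v) for v in np.clip(preds, 0.0, 1.0)]


def estimate_fnr(
    survived: np.ndarray | list[bool], trio_id: str = "", conf_level: float = 0.95
) -> FnrEstimate:
    """FNR = fraction of simulated DNMs that failed the filters, with an exact
    (Clopper-Pearson) binomial confidence interval."""
    survived = np.asarray(survived, dtype=bool)
    n = survived.size
    if n == 0:
        raise ValueError("empty simulated-DNM table")
    n_failed = int((~survived).sum())
    fnr = n_failed / n
    if fnr == 1.0:
        warnings.warn("all simulated DNMs failed the filters", stacklevel=2)
    alpha = 1 - conf_level
    lo = stats.beta.ppf(alpha / 2, n_failed, n - n_failed + 1) if n_failed > 0 else 0.0
    hi = (
        stats.beta.ppf(1 - alpha / 2, n_failed + 1, n - n_failed)
        if n_failed < n
        else 1.0
    )
    return FnrEstimate(trio_id, n, n_failed, fnr, (float(lo), float(hi)))
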