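"""End-to-end inference chain from candidate-call tables to rates and alpha.

Chains the stage modules in the order of the analysis: cluster screening,
per F1-F2 observation probabilities, transmission-based FDR maximum
likelihood (with coverage-regression imputation for F1s lacking an F2),
simulation-based FNR, phasing consensus, error-adjusted sex-specific counts,
identity-link Poisson age regressions, per-generation/per-year rates, and the
male-to-female mutation ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import dnm_filters, error_rates, phasing, rates_regression
from .error_rates import ErrorRateSet, TransmissionModel
from .rates_regression import RateEstimate, RegressionFit
from .synthetic_cohort import SimulatedCohort


@dataclass
class PipelineResult:
    error_rates: ErrorRateSet
    q_hat: dict[tuple[str, int], float]
    adjusted: pd.DataFrame  # trio_id, sex, upsilon, age
    fit_male: RegressionFit
    fit_female: RegressionFit
    per_generation: dict[str, RateEstimate]
    yearly: RateEstimate
    alpha_counts: dict
    alpha_fitted: dict
    phased: pd.DataFrame = field(repr=False, default=None)


def _parse_f2_obs(value: str) -> list[bool]:
    if not value:
        return []
    return [v == "1" for v in value.split(",")]


def _phase_calls(df: pd.DataFrame) -> list[phasing.PhaseCall]:
    calls = []
    for idx, f2_str, trans_phase, rb in zip(
        df.index, df["f2_observed"], df["transmission_phase"], df["readbacked_phase"]
    ):
        trans = [
            trans_phase if seen and trans_phase in ("paternal", "maternal") else "none"
            for seen in _parse_f2_obs(f2_str)
        ]
        calls.append(
            phasing.PhaseCall(
                dnm_id=str(idx),
                readbacked=rb if rb in ("paternal", "maternal", "ambiguous") else "none",
                transmission=trans,
            )
        )
    return calls


def run_pipeline(
    cohort: SimulatedCohort,
    G_m: float,
    G_f: float,
    n_draws: int = 1000,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
) -> PipelineResult:
    """Run the full chain on a simulated cohort and report rates at typical
    conception ages (G_m, G_f).

    The cohort's parental ages are ages at conception, so the age regressions
    use them directly (gestation offset zero).
    """
    rng = np.random.default_rng() if rng is None else rng
    spec = cohort.spec
    H = spec.haploid_size
    O = spec.orthologous_size
    gmap = cohort.genetic_map

    # 1. cluster screen -----------------------------------------------------
    clustered = dnm_filters.detect_clusters_by_trio(cohort.candidates)
    retained = dnm_filters.remove_large_clusters(clustered)

    # 2. observation probabilities from the transmission simulations --------
    q_hat: dict[tuple[str, int], float] = {}
    for row in cohort.transmission_sim.itertuples(index=False):
        q_hat[(row.trio_id, row.f2_index)] = error_rates.estimate_q(
            row.n_observed, row.n_eligible
        )

    # 3. per-trio error rates ----------------------------------------------
    ers = ErrorRateSet()
    doublet_y: dict[str, int] = {}
    doublet_z = 0
    trios = sorted(cohort.ages["trio_id"])
    m_by_trio = dict(zip(cohort.ages["trio_id"], cohort.ages["m_f2"]))
    no_f2: list[str] = []
    for trio in trios:
        sub = retained[retained["trio_id"] == trio]
        singlets = sub[sub["cluster_size"] == 1]
        doublets = sub[sub["cluster_size"] == 2]
        m = int(m_by_trio[trio])
        obs = np.array([_parse_f2_obs(v) for v in singlets["f2_observed"]]).reshape(
            len(singlets), m if m else 0
        )
        doublet_y[trio] = len(doublets)
        if len(doublets):
            # a doublet transmits only when both members do, in the same F2
            d_obs = np.array(
                [_parse_f2_obs(v) for v in doublets["f2_observed"]]
            ).reshape(len(doublets), m if m else 0)
            for cid, grp in doublets.groupby("cluster_id"):
                rows = [doublets.index.get_loc(i) for i in grp.index]
                if m and np.all(d_obs[rows], axis=0).any():
                    doublet_z += len(rows)
        if m == 0:
            no_f2.append(trio)
            continue
        q = tuple(q_hat[(trio, j)] for j in range(m))
        model = TransmissionModel(trio_id=trio, q=q)
        y1 = len(singlets)
        if m == 1:
            z = int(obs[:, 0].sum()) if y1 else 0
        else:
            both = (obs[:, 0] & obs[:, 1]).sum() if y1 else 0
            first = (obs[:, 0] & ~obs[:, 1]).sum() if y1 else 0
            second = (~obs[:, 0] & obs[:, 1]).sum() if y1 else 0
            z = (int(first), int(second), int(both))
        ers.singlet_fdr[trio] = error_rates.fdr_singlet_mle(y1, z, model)
        fnr_tab = cohort.filter_sim[cohort.filter_sim["trio_id"] == trio]
        ers.fnr[trio] = error_rates.estimate_fnr(
            fnr_tab["survived"].to_numpy(), trio_id=trio
        )
    for trio in no_f2:
        fnr_tab = cohort.filter_sim[cohort.filter_sim["trio_id"] == trio]
        ers.fnr[trio] = error_rates.estimate_fnr(
            fnr_tab["survived"].to_numpy(), trio_id=trio
        )
    if no_f2:
        depth = {ind.id: ind.mean_depth for ind in cohort.pedigree.individuals}
        known = [
            (depth[f"{t}_F1"], ers.singlet_fdr[t].fdr)
            for t in trios
            if t in ers.singlet_fdr
        ]
        imputed = error_rates.impute_fdr_from_coverage(
            known, [depth[f"{t}_F1"] for t in no_f2]
        )
        for trio, fdr in zip(no_f2, imputed):
            ers.singlet_fdr[trio] = error_rates.FdrEstimate(
                trio_id=trio, y=0, w_hat=0, fdr=fdr, loglik=np.nan, imputed=True
            )
    q_bar = float(np.mean(list(q_hat.values())))
    ers.doublet_fdr = error_rates.fdr_doublet_pooled(doublet_y, doublet_z, q_bar)
    fdr2 = ers.doublet_fdr.fdr if ers.doublet_fdr is not None else 0.0

    # 4. phasing consensus --------------------------------------------------
    calls = _phase_calls(retained)
    phasing.consensus_table(calls)
    retained = retained.assign(consensus=[c.consensus for c in calls])

    # 5. adjusted counts and regressions ------------------------------------
    adjusted_rows = []
    for trio in trios:
        sub = retained[retained["trio_id"] == trio]
        sub_calls = [c for c, t in zip(calls, retained["trio_id"]) if t == trio]
        m = int(m_by_trio[trio])
        try:
            frac = phasing.phased_fraction(sub_calls, restrict_to_transmitted=m > 0)
            a_m = frac["fraction_paternal"]
        except ValueError:
            # no phased DNMs in this trio: fall back to the cohort-wide fraction
            frac_all = phasing.phased_fraction(calls, restrict_to_transmitted=False)
            a_m = frac_all["fraction_paternal"]
        y1 = int((sub["cluster_size"] == 1).sum())
        y2 = int((sub["cluster_size"] == 2).sum())
        ages_row = cohort.ages.loc[cohort.ages["trio_id"] == trio].iloc[0]
        for sex, a_s, age in (
            ("male", a_m, ages_row["father_age"]),
            ("female", 1 - a_m, ages_row["mother_age"]),
        ):
            adj = rates_regression.adjust_counts(
                y1,
                y2,
                ers.singlet_fdr[trio].fdr,
                fdr2,
                ers.fnr[trio].fnr,
                a_s,
                O,
                H,
                trio_id=trio,
                sex=sex,
            )
            adjusted_rows.append(
                {"trio_id": trio, "sex": sex, "upsilon": adj.upsilon, "age": age}
            )
    adjusted = pd.DataFrame(adjusted_rows)

    fits = {}
    for sex in ("male", "female"):
        sub = adjusted[(adjusted["sex"] == sex) & adjusted["age"].notna()]
        fits[sex] = rates_regression.fit_age_model(
            sub["upsilon"].to_numpy(),
            sub["age"].to_numpy(),
            gestation=0.0,
            sex=sex,
            species=spec.species,
        )

    per_gen = rates_regression.per_generation_rate(
        fits["male"], fits["female"], G_m, G_f, H, n_draws=n_draws, rng=rng
    )
    yearly = rates_regression.yearly_rate(per_gen, G_m, G_f)

    transmitted = retained[
        retained["consensus"].isin(["paternal", "maternal"])
        & retained["f2_observed"].str.contains("1")
    ]
    alpha_counts = rates_regression.alpha_from_phased(
        transmitted, gmap, n_boot=n_boot, rng=rng
    )
    alpha_fit = rates_regression.alpha_fitted(
        fits["male"], fits["female"], G_m, G_f, n_draws=n_draws, rng=rng
    )

    return PipelineResult(
        error_rates=ers,
        q_hat=q_hat,
        adjusted=adjusted,
        fit_male=fits["male"],
        fit_female=fits["female"],
        per_generation=per_gen,
        yearly=yearly,
        alpha_counts=alpha_counts,
        alpha_fitted=alpha_fit,
        phased=retained,
    )
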