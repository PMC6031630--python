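"""Full-pipeline execution and cohort-level summary statistics.

Runs dose accumulation, risk projection and cost accounting over a cohort
and reduces the per-patient records to the summary surfaces of interest:
per-organ cumulative-dose distributions, per-site lifetime-attributable-risk
summaries, and per-region cost percentiles, plus a Mann-Whitney rank-sum
comparison for two-group contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import risk as risk_mod
from .cohort import SyntheticCohort
from .cost import CostStatement, FeeSchedule, patient_cost
from .dose import (DoseParamTable, ExposureSummary, ProcedureHistory,
                   cumulative_dose, frame_to_histories)
from .risk import LifeTable, RiskCoefficients

#: Cost box-plot percentiles (paper-style box plots: 10/25/50/75/90).
COST_PERCENTILES = (10, 25, 50, 75, 90)

#: Default cumulative-dose histogram bin edges (cGy): 0-5, 5-15, 15-25, ...
#: with an open top bin.
def default_dose_bin_edges(max_dose: float) -> np.ndarray:
    top = max(15.0, 10.0 * np.ceil((max_dose + 5.0) / 10.0) + 5.0)
    return np.concatenate([[0.0], np.arange(5.0, top + 1e-9, 10.0)])


@dataclass(frozen=True)
class OrganDoseStats:
    n: int
    mean_cGy: float
    min_cGy: float
    max_cGy: float
    frac_le_50: float
    frac_ge_100: float
    frac_gt_10: float


@dataclass(frozen=True)
class SiteRiskStats:
    n: int
    mean_per_100k: float
    min_per_100k: float
    max_per_100k: float


@dataclass(frozen=True)
class CohortSummary:
    """Aggregate statistics over one pipeline run."""

    n_patients: int
    n_organs: int
    n_excluded: int
    excluded_ids: tuple[str, ...]
    organ_dose: Mapping[str, OrganDoseStats]
    site_risk: Mapping[str, SiteRiskStats]
    cost_percentiles_by_region: Mapping[str, Mapping[int, float]]
    cost_percentiles_overall: Mapping[int, float]


@dataclass(frozen=True)
class PipelineResult:
    summary: CohortSummary
    exposures: pd.DataFrame   # one row per (patient, organ)
    risks: pd.DataFrame       # one row per (patient, site)
    costs: pd.DataFrame       # one row per patient


def _organ_stats(doses: np.ndarray) -> OrganDoseStats:
    # sorted before reduction so aggregation is exactly permutation-invariant
    doses = np.sort(doses)
    return OrganDoseStats(
        n=len(doses),
        mean_cGy=float(doses.mean()),
        min_cGy=float(doses.min()),
        max_cGy=float(doses.max()),
        frac_le_50=float((doses <= 50.0).mean()),
        frac_ge_100=float((doses >= 100.0).mean()),
        frac_gt_10=float((doses > 10.0).mean()),
    )


def run_pipeline(cohort: SyntheticCohort | Iterable[ProcedureHistory] | pd.DataFrame,
                 dose_params: DoseParamTable,
                 risk_coeffs: Mapping[tuple[str, str], RiskCoefficients],
                 life_tables: Mapping[str, LifeTable],
                 fee_schedule: FeeSchedule,
                 include_ct: bool = True) -> PipelineResult:
    """Dose -> risk -> cost over a cohort, with aggregate summary.

    Accepts a synthetic cohort, a list of per-organ histories, or a raw
    cohort DataFrame.  DataFrame rows failing validation are excluded and
    reported by patient id in the summary, never dropped silently.
    """
    excluded: list[str] = []
    if isinstance(cohort, SyntheticCohort):
        histories = cohort.histories
    elif isinstance(cohort, pd.DataFrame):
        histories = []
        for _, row in cohort.iterrows():
            try:
                histories.extend(frame_to_histories(row.to_frame().T))
            except (ValueError, TypeError):
                excluded.append(str(row.get("patient_id", "<unknown>")))
    else:
        histories = list(cohort)

    exposures: list[ExposureSummary] = [
        cumulative_dose(h, dose_params, include_ct=include_ct)
        for h in histories
    ]
    exp_rows = [
        {
            "patient_id": x.patient_id, "organ": x.organ, "sex": x.sex,
            "age_at_exposure": x.age_at_exposure,
            "cumulative_dose_cGy": x.cumulative_dose_cGy,
            "equivalent_dose_Sv": x.equivalent_dose_Sv,
        }
        for x in exposures
    ]
    exp_df = pd.DataFrame(exp_rows, columns=[
        "patient_id", "organ", "sex", "age_at_exposure",
        "cumulative_dose_cGy", "equivalent_dose_Sv"])

    risk_rows = []
    for x in exposures:
        site = risk_mod.ORGAN_SITE[x.organ]
        r = risk_mod.lar(x, risk_coeffs[(site, x.sex)], life_tables[x.sex])
        risk_rows.append({
            "patient_id": x.patient_id, "site": site, "sex": x.sex,
            "age_at_exposure": x.age_at_exposure, "dose_Sv": r.dose_Sv,
            "lar_per_person": r.lar_per_person,
            "lar_per_100k": r.lar_per_100k,
        })
    risk_df = pd.DataFrame(risk_rows, columns=[
        "patient_id", "site", "sex", "age_at_exposure", "dose_Sv",
        "lar_per_person", "lar_per_100k"])

    by_patient: dict[str, list[ProcedureHistory]] = {}
    for h in histories:
        by_patient.setdefault(h.patient_id, []).append(h)
    cost_rows = []
    for pid, hs in by_patient.items():
        stmt = patient_cost(hs, fee_schedule)
        cost_rows.append({
            "patient_id": pid,
            "regions": "+".join(sorted({h.region for h in hs})),
            "total_usd": stmt.total_usd,
        })
    cost_df = pd.DataFrame(cost_rows, columns=["patient_id", "regions",
                                               "total_usd"])

    organ_dose = {}
    if len(exp_df):
        for organ, g in exp_df.groupby("organ", sort=True):
            organ_dose[organ] = _organ_stats(g["cumulative_dose_cGy"].to_numpy())
    site_risk = {}
    if len(risk_df):
        for site, g in risk_df.groupby("site", sort=True):
            v = np.sort(g["lar_per_100k"].to_numpy())
            site_risk[site] = SiteRiskStats(
                n=len(v), mean_per_100k=float(v.mean()),
                min_per_100k=float(v.min()), max_per_100k=float(v.max()))

    cost_by_region: dict[str, dict[int, float]] = {}
    cost_overall: dict[int, float] = {}
    if len(cost_df):
        totals = cost_df["total_usd"].to_numpy()
        cost_overall = {p: float(np.percentile(totals, p, method="linear"))
                        for p in COST_PERCENTILES}
        for region in ("head", "thorax", "pelvis"):
            pids = {h.patient_id for h in histories if h.region == region}
            sub = cost_df[cost_df["patient_id"].isin(pids)]["total_usd"].to_numpy()
            if len(sub):
                cost_by_region[region] = {
                    p: float(np.percentile(sub, p, method="linear"))
                    for p in COST_PERCENTILES}

    summary = CohortSummary(
        n_patients=len(by_patient),
        n_organs=len(histories),
        n_excluded=len(excluded),
        excluded_ids=tuple(excluded),
        organ_dose=organ_dose,
        site_risk=site_risk,
        cost_percentiles_by_region=cost_by_region,
        cost_percentiles_overall=cost_overall,
    )
    return PipelineResult(summary=summary, exposures=exp_df, risks=risk_df,
                          costs=cost_df)


def compare_groups(values_a: Sequence[float],
                   values_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney rank-sum test with tie correction.

    Returns ``(U statistic, p-value)``; the conventional significance
    threshold for these comparisons is 0.05.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def dose_histogram(doses: Sequence[float],
                   edges: Sequence[float] | None = None
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Counts per cumulative-dose bin; the top bin is open-ended.

    Returns ``(counts, edges)`` where ``counts`` has one more entry than
    inner bins to hold the open top bin (doses >= last edge).
    """
    d = np.asarray(doses, dtype=float)
    if edges is None:
        edges = default_dose_bin_edges(float(d.max()) if len(d) else 0.0)
    edges = np.asarray(edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    counts, _ = np.histogram(d, bins=np.concatenate([edges, [np.inf]]))
    return counts, edges
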