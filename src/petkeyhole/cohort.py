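"""Cohort-level analysis: pipeline orchestration, deviation counts and
Spearman correlation of imaging changes with PSA changes.

The per-patient pipeline is segmentation -> keyhole reduction -> response
classification; the cohort layer joins PSA, grades whole-body vs reduced
discrepancies, and produces the two summary products:

* deviation counts per (metric family, k): how many patients are
  concordant / non-relevantly discordant / clinically relevantly discordant
  between the whole-body metric and its top-k reduction;
* a correlation table of delta-PSA against each imaging delta (whole-body,
  top-10, top-5, hottest lesion), using Spearman's rank correlation with a
  two-sided p-value, significant at p < 0.05.

The Spearman statistic is computed as the Pearson correlation of mid-ranks
(average ranks on ties). The p-value uses exact permutation enumeration for
n <= 10 and the t-approximation ``t = r*sqrt((n-2)/(1-r^2))`` above that;
the crossover is covered by a test.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special
from scipy.stats import rankdata

from .exceptions import ConstantInputError, EmptyCohortError
from .keyhole import DeltaMetrics, metric_name, patient_metrics, relative_change
from .response import DeviationVerdict, ResponseCall, assess_deviation, classify_response

__all__ = [
    "SpearmanResult",
    "PatientAssessment",
    "CohortSummary",
    "spearman",
    "assess_patient",
    "assemble_cohort",
    "assemble_from_tables",
    "summarize",
    "SIGNIFICANCE_LEVEL",
    "EXACT_P_MAX_N",
]

logger = logging.getLogger(__name__)

SIGNIFICANCE_LEVEL = 0.05
#: exact permutation p-values up to this sample size, t-approximation above
EXACT_P_MAX_N = 10

#: correlation-table row layout: subset label -> (family, subset key)
CORRELATION_ROWS = [
    ("total", "volume", "all"),
    ("ten largest", "volume", 10),
    ("five largest", "volume", 5),
    ("total", "suvmax", "all"),
    ("ten hottest", "suvmax", 10),
    ("five hottest", "suvmax", 5),
    ("hottest lesion", "suvmax", 1),
]

_VERDICT_PAIRS = [("suvmax", 10), ("suvmax", 5), ("volume", 10), ("volume", 5)]


@dataclass(frozen=True)
class SpearmanResult:
    r: float
    p: float
    n: int
    method: str  # 'exact' or 't-approx'

    @property
    def significant(self) -> bool:
        return self.p < SIGNIFICANCE_LEVEL


def _rank_correlation(rx: np.ndarray, ry: np.ndarray) -> float:
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = math.sqrt(float(rxc @ rxc) * float(ryc @ ryc))
    return float(rxc @ ryc) / denom


def spearman(x, y) -> SpearmanResult:
    """Spearman rank correlation with a two-sided p-value.

    r is the Pearson correlation of mid-ranks. For n <= 10 the p-value is
    the exact two-sided permutation probability P(|r_perm| >= |r_obs|) over
    all n! permutations of one margin; for larger n the usual Student-t
    approximation with n-2 degrees of freedom is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
        raise ValueError("missing or non-finite values are not allowed")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("Spearman correlation undefined for a constant vector")
    rx = rankdata(x, method="average")
    ry = rankdata(y, method="average")
    r = _rank_correlation(rx, ry)

    if n <= EXACT_P_MAX_N:
        # exact enumeration: permute one margin's ranks, count |r| >= |r_obs|
        perms = np.array(list(itertools.permutations(ry)))
        rxc = rx - rx.mean()
        denom = math.sqrt(
            float(rxc @ rxc) * float(((ry - ry.mean()) ** 2).sum())
        )
        stats = (perms - ry.mean()) @ rxc / denom
        count = int(np.count_nonzero(np.abs(stats) >= abs(r) - 1e-12))
        p = count / len(perms)
        method = "exact"
    else:
        r_clamped = min(1.0 - 1e-15, abs(r))
        if r_clamped >= 1.0:
            p = 0.0
        else:
            t = r_clamped * math.sqrt((n - 2) / (1.0 - r_clamped**2))
            # two-sided p from Student t with n-2 df
            p = float(2.0 * special.stdtr(n - 2, -t))
        method = "t-approx"
    return SpearmanResult(r=r, p=p, n=n, method=method)


@dataclass(frozen=True)
class PatientAssessment:
    """Everything the cohort summary needs for one patient."""

    patient_id: str
    metrics: DeltaMetrics
    delta_psa_pct: float
    calls: dict  # (family, subset) -> ResponseCall
    verdicts: dict  # (family, k) -> DeviationVerdict
    cohort: str = "custom"

    @property
    def fewer_than_5_lesions(self) -> bool:
        """Asterisk flag: fewer than five baseline lesions."""
        return self.metrics.n_baseline < 5


def assess_patient(
    patient_id: str,
    baseline_lesions,
    followup_lesions,
    psa_baseline: float,
    psa_followup: float,
    cohort: str = "custom",
    ks=(10, 5),
) -> PatientAssessment:
    """Run keyhole reduction + classification for one patient and join PSA."""
    metrics = patient_metrics(baseline_lesions, followup_lesions, ks=ks)
    delta_psa = relative_change(psa_baseline, psa_followup)
    calls = {
        key: classify_response(metrics.deltas[key], metric=metric_name(*key))
        for key in metrics.deltas
    }
    verdicts = {
        (family, k): assess_deviation(calls[(family, "all")], calls[(family, k)])
        for family, k in _VERDICT_PAIRS
        if (family, k) in calls
    }
    return PatientAssessment(
        patient_id=patient_id,
        metrics=metrics,
        delta_psa_pct=delta_psa,
        calls=calls,
        verdicts=verdicts,
        cohort=cohort,
    )


def assemble_from_tables(
    lesion_table: pd.DataFrame,
    psa_table: pd.DataFrame,
    cohort_labels: dict | None = None,
    ks=(10, 5),
) -> tuple[list[PatientAssessment], list[dict]]:
    """Assemble patient assessments from a lesion table and a PSA table.

    Patients missing a timepoint or a PSA value are excluded; each exclusion
    is logged and reported in the second return value, never silently
    dropped.
    """
    if len(psa_table) == 0 and len(lesion_table) == 0:
        raise EmptyCohortError("no patients to assemble")
    psa = psa_table.set_index(psa_table["patient_id"].astype(str))
    assessments: list[PatientAssessment] = []
    excluded: list[dict] = []
    patient_ids = sorted(lesion_table["patient_id"].astype(str).unique())
    if not patient_ids:
        raise EmptyCohortError("lesion table contains no patients")
    for pid in patient_ids:
        sub = lesion_table[lesion_table["patient_id"].astype(str) == pid]
        bl = sub[sub["timepoint"] == "baseline"]
        fu = sub[sub["timepoint"] == "followup"]
        reason = None
        if len(bl) == 0:
            reason = "missing baseline timepoint"
        elif len(fu) == 0:
            reason = "missing followup timepoint"
        elif pid not in psa.index:
            reason = "missing PSA record"
        else:
            row = psa.loc[pid]
            if not np.isfinite(row["psa_baseline"]) or not np.isfinite(row["psa_followup"]):
                reason = "non-finite PSA value"
        if reason is not None:
            logger.warning("excluding patient %s: %s", pid, reason)
            excluded.append({"patient_id": pid, "reason": reason})
            continue
        row = psa.loc[pid]
        cohort = (cohort_labels or {}).get(pid, "custom")
        assessments.append(
            assess_patient(
                pid, bl, fu,
                float(row["psa_baseline"]), float(row["psa_followup"]),
                cohort=cohort, ks=ks,
            )
        )
    if not assessments and excluded:
        raise EmptyCohortError(
            f"all {len(excluded)} patients excluded: {excluded}"
        )
    return assessments, excluded


def assemble_cohort(
    cohort_spec,
    psa_table: pd.DataFrame | None = None,
    *,
    threshold_mode: str = "liver",
    connectivity: int = 26,
    min_voxels: int = 1,
    ks=(10, 5),
    cohort_label: str = "custom",
) -> tuple[list[PatientAssessment], list[dict]]:
    """Run the full imaging pipeline on a synthetic cohort specification.

    For each patient both scans are rasterized, the reference-ROI statistics
    and threshold are computed per scan (PERCIST convention), reference
    regions are excluded from segmentation, and the keyhole assessment is
    performed. Returns (assessments, exclusions).
    """
    from .model import segment_cohort  # runtime import avoids a module cycle

    if len(cohort_spec.patients) == 0:
        raise EmptyCohortError("cohort specification contains no patients")
    psa = psa_table if psa_table is not None else cohort_spec.psa_table
    lesion_table = segment_cohort(
        cohort_spec,
        threshold_mode=threshold_mode,
        connectivity=connectivity,
        min_voxels=min_voxels,
    )
    labels = {case.patient_id: cohort_label for case in cohort_spec.patients}
    return assemble_from_tables(lesion_table, psa, cohort_labels=labels, ks=ks)


@dataclass(frozen=True)
class CohortSummary:
    """Deviation counts, correlation table and waterfall export for one run."""

    deviation_counts: pd.DataFrame
    correlations: pd.DataFrame
    waterfall: pd.DataFrame
    n_patients: int


def per_patient_table(assessments: list[PatientAssessment]) -> pd.DataFrame:
    """One row per patient: all deltas, calls, verdicts and the PSA change."""
    rows = []
    for a in assessments:
        row = {"patient_id": a.patient_id, "cohort": a.cohort}
        row.update(a.metrics.as_row())
        row["delta_psa_pct"] = a.delta_psa_pct
        for key, call in a.calls.items():
            row[f"call_{metric_name(*key)}"] = call.label
        for (family, k), verdict in a.verdicts.items():
            name = metric_name(family, k)
            row[f"deviation_{name}"] = verdict.verdict
        row["fewer_than_5_lesions"] = a.fewer_than_5_lesions
        rows.append(row)
    return pd.DataFrame(rows)


def summarize(
    assessments: list[PatientAssessment], min_n_correlation: int = 3
) -> CohortSummary:
    """Reduce patient assessments to cohort-level tables.

    Deviation counts always satisfy concordant + non_relevant + relevant = n
    per (metric family, k). Correlation cells are computed per cohort label
    when at least ``min_n_correlation`` patients are available, otherwise
    reported as missing (NaN) rather than failing; a constant input likewise
    yields a missing cell.
    """
    if not assessments:
        raise EmptyCohortError("cannot summarize an empty cohort")
    cohorts = sorted({a.cohort for a in assessments})

    dev_rows = []
    for cohort in cohorts:
        group = [a for a in assessments if a.cohort == cohort]
        for family, k in _VERDICT_PAIRS:
            counts = {"concordant": 0, "non_relevant": 0, "relevant": 0}
            for a in group:
                counts[a.verdicts[(family, k)].verdict] += 1
            dev_rows.append(
                {
                    "cohort": cohort,
                    "metric": "PSMA-TV" if family == "volume" else "SUVmax",
                    "k": k,
                    "n": len(group),
                    **counts,
                }
            )
    deviation_counts = pd.DataFrame(dev_rows)

    corr_rows = []
    for cohort in cohorts:
        group = [a for a in assessments if a.cohort == cohort]
        dpsa = np.array([a.delta_psa_pct for a in group])
        for label, family, subset in CORRELATION_ROWS:
            deltas = np.array([a.metrics.deltas[(family, subset)] for a in group])
            r = p = np.nan
            n = len(group)
            sig = None
            if n >= min_n_correlation:
                try:
                    res = spearman(deltas, dpsa)
                    r, p, sig = res.r, res.p, res.significant
                except ConstantInputError:
                    logger.warning(
                        "constant input for %s/%s in cohort %s; correlation cell "
                        "reported missing", family, subset, cohort,
                    )
            corr_rows.append(
                {
                    "cohort": cohort,
                    "metric": "PSMA-TV" if family == "volume" else "SUVmax",
                    "subset": label,
                    "spearman_r": r,
                    "p_value": p,
                    "significant": sig,
                    "n": n,
                }
            )
    correlations = pd.DataFrame(corr_rows)

    wf_rows = []
    for a in assessments:
        for family in ("suvmax", "volume"):
            wf_rows.append(
                {
                    "cohort": a.cohort,
                    "patient_id": a.patient_id,
                    "metric": "PSMA-TV" if family == "volume" else "SUVmax",
                    "delta_all_pct": a.metrics.deltas[(family, "all")],
                    "delta_10_pct": a.metrics.deltas[(family, 10)],
                    "delta_5_pct": a.metrics.deltas[(family, 5)],
                    "fewer_than_5_lesions": a.fewer_than_5_lesions,
                    "reference_line_pct": 30.0,
                }
            )
    waterfall = (
        pd.DataFrame(wf_rows)
        .sort_values(["cohort", "metric", "delta_all_pct"], ascending=[True, True, False])
        .reset_index(drop=True)
    )
    return CohortSummary(
        deviation_counts=deviation_counts,
        correlations=correlations,
        waterfall=waterfall,
        n_patients=len(assessments),
    )
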