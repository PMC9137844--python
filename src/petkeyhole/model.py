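"""Study-level modelling objects.

:class:`KeyholeStudy` is the package's front door: it is built from the two
on-disk artifacts of a study — a lesion table (one row per segmented lesion
per patient and timepoint) and a PSA table — and ``fit()`` runs the keyhole
assessment for every patient, returning a :class:`KeyholeStudyResults` that
carries the per-patient deltas and response calls, the deviation counts,
the PSA correlation table and a ``summary()`` view. Simulation
(:meth:`KeyholeStudy.simulate`) and waterfall plotting hang off these two
objects.

Example
-------
>>> study = KeyholeStudy.simulate(n_patients=16, seed=7)
>>> res = study.fit()
>>> print(res.summary())          # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as _cohort
from .io import read_lesion_table, validate_lesion_table

__all__ = ["KeyholeStudy", "KeyholeStudyResults"]


class KeyholeStudy:
    """A baseline/follow-up PSMA PET response study.

    Parameters
    ----------
    lesion_table
        DataFrame with the package's lesion-table schema
        (patient_id, timepoint, lesion_id, suvmax, volume_ml, centroid_*).
    psa_table
        DataFrame with columns patient_id, psa_baseline, psa_followup.
    cohort_labels
        Optional mapping patient_id -> cohort label (e.g. 'mHSPC',
        'taxane', 'RLT'); unlabeled patients fall into 'custom'.
    ks
        The reduction sizes (default (10, 5)).
    """

    def __init__(
        self,
        lesion_table: pd.DataFrame,
        psa_table: pd.DataFrame,
        cohort_labels: dict | None = None,
        ks=(10, 5),
    ) -> None:
        self.lesion_table = validate_lesion_table(lesion_table)
        self.psa_table = psa_table
        self.cohort_labels = cohort_labels or {}
        self.ks = tuple(ks)

    @classmethod
    def from_csv(
        cls,
        lesion_csv: str | Path,
        psa_csv: str | Path,
        cohort_labels: dict | None = None,
        ks=(10, 5),
    ) -> "KeyholeStudy":
        lesions = read_lesion_table(lesion_csv)
        psa = pd.read_csv(psa_csv, dtype={"patient_id": str})
        return cls(lesions, psa, cohort_labels=cohort_labels, ks=ks)

    @classmethod
    def simulate(
        cls,
        n_patients: int,
        seed: int,
        target_rank_coupling: float = 0.6,
        cohort_config=None,
        threshold_mode: str = "liver",
        connectivity: int = 26,
        cohort_label: str = "custom",
    ) -> "KeyholeStudy":
        """Generate a synthetic cohort, run segmentation on every scan, and
        return a study built from the resulting lesion and PSA tables."""
        from .synthetic import generate_cohort

        spec = generate_cohort(
            n_patients, seed, target_rank_coupling=target_rank_coupling,
            config=cohort_config,
        )
        lesion_table = segment_cohort(
            spec, threshold_mode=threshold_mode, connectivity=connectivity
        )
        labels = {p.patient_id: cohort_label for p in spec.patients}
        study = cls(lesion_table, spec.psa_table, cohort_labels=labels)
        study.cohort_spec = spec  # ground truth kept for validation studies
        return study

    def fit(self) -> "KeyholeStudyResults":
        """Run the keyhole assessment for every patient."""
        assessments, excluded = _cohort.assemble_from_tables(
            self.lesion_table, self.psa_table,
            cohort_labels=self.cohort_labels, ks=self.ks,
        )
        summary = _cohort.summarize(assessments)
        return KeyholeStudyResults(
            model=self, assessments=assessments, excluded=excluded, _summary=summary
        )


def segment_cohort(
    cohort_spec,
    threshold_mode: str = "liver",
    connectivity: int = 26,
    min_voxels: int = 1,
) -> pd.DataFrame:
    """Rasterize and segment every scan of a synthetic cohort into a lesion table."""
    from .segmentation import (
        compute_threshold,
        reference_roi_stats,
        roi_mask,
        segment_lesions,
    )
    from .synthetic import followup_config, generate_phantom

    tables = []
    for case in cohort_spec.patients:
        for timepoint, cfg in (
            ("baseline", case.baseline_config),
            ("followup", followup_config(case.baseline_config, case.scenario)),
        ):
            volume, rois, _ = generate_phantom(cfg)
            roi_key = "liver" if threshold_mode == "liver" else "aorta"
            mean, sd = reference_roi_stats(volume, rois[roi_key])
            threshold = compute_threshold(mean, sd, mode=threshold_mode)
            exclusion = np.zeros(volume.shape, dtype=bool)
            for spec in rois.values():
                exclusion |= roi_mask(volume, spec)
            lesion_set = segment_lesions(
                volume, threshold, exclusion,
                connectivity=connectivity, min_voxels=min_voxels,
            )
            tables.append(lesion_set.to_table(case.patient_id, timepoint))
    tables = [t for t in tables if len(t)]
    if not tables:
        from .io import LESION_TABLE_COLUMNS

        return pd.DataFrame(columns=LESION_TABLE_COLUMNS)
    return pd.concat(tables, ignore_index=True)


@dataclass
class KeyholeStudyResults:
    """Fitted results of a :class:`KeyholeStudy`."""

    model: KeyholeStudy
    assessments: list
    excluded: list
    _summary: _cohort.CohortSummary

    # -- tabular views ------------------------------------------------------
    @property
    def per_patient(self) -> pd.DataFrame:
        """One row per patient: deltas, calls, verdicts, PSA change."""
        return _cohort.per_patient_table(self.assessments)

    @property
    def deviation_counts(self) -> pd.DataFrame:
        return self._summary.deviation_counts

    @property
    def correlations(self) -> pd.DataFrame:
        return self._summary.correlations

    @property
    def waterfall(self) -> pd.DataFrame:
        """Sorted per-patient changes for waterfall-style plots, with the
        ±30% reference level and the <5-lesion flag."""
        return self._summary.waterfall

    @property
    def n_patients(self) -> int:
        return self._summary.n_patients

    def relevant_deviation_count(self, metric: str, k: int) -> int:
        """Number of clinically relevant deviations for a (metric, k) pair.

        ``metric`` is 'PSMA-TV' or 'SUVmax'.
        """
        df = self.deviation_counts
        row = df[(df["metric"] == metric) & (df["k"] == k)]
        return int(row["relevant"].sum())

    # -- presentation -------------------------------------------------------
    def summary(self) -> str:
        """Human-readable summary: cohort sizes, deviation counts, and the
        correlation table in the total/ten/five row layout."""
        lines = []
        lines.append("Keyhole response assessment")
        lines.append("=" * 60)
        lines.append(f"patients assessed: {self.n_patients}"
                     + (f" (excluded: {len(self.excluded)})" if self.excluded else ""))
        n_ast = sum(a.fewer_than_5_lesions for a in self.assessments)
        lines.append(f"patients with <5 baseline lesions: {n_ast}")
        lines.append("")
        lines.append("Deviations of reduced vs whole-body classification")
        lines.append("-" * 60)
        lines.append(self.deviation_counts.to_string(index=False))
        lines.append("")
        lines.append("Spearman correlation with deltaPSA (p < 0.05 significant)")
        lines.append("-" * 60)
        corr = self.correlations.copy()
        corr["spearman_r"] = corr["spearman_r"].round(2)
        corr["p_value"] = corr["p_value"].round(4)
        lines.append(corr.to_string(index=False))
        return "\n".join(lines)

    def plot_waterfall(self, metric: str = "PSMA-TV", cohort: str | None = None, ax=None):
        """Waterfall plot of per-patient relative changes for one metric.

        Whole-body changes as bars, top-10/top-5 as markers, dotted ±30%
        reference lines, asterisks under patients with <5 lesions.
        """
        import matplotlib.pyplot as plt

        wf = self.waterfall
        wf = wf[wf["metric"] == metric]
        if cohort is not None:
            wf = wf[wf["cohort"] == cohort]
        wf = wf.sort_values("delta_all_pct", ascending=False).reset_index(drop=True)
        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        x = np.arange(len(wf))
        ax.bar(x, wf["delta_all_pct"], color="seagreen", label="all lesions")
        ax.plot(x, wf["delta_10_pct"], "s", color="gray", label="top 10")
        ax.plot(x, wf["delta_5_pct"], "^", color="royalblue", label="top 5")
        for level in (30.0, -30.0):
            ax.axhline(level, linestyle=":", color="black", linewidth=1)
        labels = [
            f"{pid}*" if flag else pid
            for pid, flag in zip(wf["patient_id"], wf["fewer_than_5_lesions"])
        ]
        ax.set_xticks(x)
        ax.set_xticklabels(labels, rotation=90, fontsize=7)
        ax.set_ylabel(f"relative change of {metric} (%)")
        ax.legend(frameon=False)
        return ax
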