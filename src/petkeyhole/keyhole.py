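"""The keyhole reduction: top-k lesion subsets and relative changes.

Instead of re-segmenting the whole body at follow-up and comparing complete
tumor burdens, the keyhole approach compares only the k hottest lesions
(by SUVmax) or the k largest lesions (by volume), with k = 10 and k = 5.
For any summed quantity X the therapy-induced relative change is

    rel. dX(%) = X_followup / X_baseline * 100 - 100

so dX = +30 means a 30% increase and dX = -100 total disappearance.

Top-k subsets are selected independently at each timepoint: lesions are
ranked per scan and the package performs no anatomical lesion matching
between baseline and follow-up, so new follow-up lesions compete for the
top-k on equal footing. This is the largest semantic choice in the module
and is deliberate — the summed metrics are per-scan rankings. If a patient
has fewer than k lesions, all lesions are used (such patients are flagged
downstream).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .exceptions import UndefinedBaselineError
from .segmentation import Lesion, LesionSet

__all__ = [
    "LesionRecord",
    "DeltaMetrics",
    "select_top_k",
    "summed_metric",
    "relative_change",
    "patient_metrics",
    "as_records",
]

_CRITERIA = ("suvmax", "volume")


@dataclass(frozen=True)
class LesionRecord:
    """Minimal per-lesion record the keyhole operations need."""

    lesion_id: int
    suvmax: float
    volume_ml: float


def as_records(lesions) -> list[LesionRecord]:
    """Normalize a LesionSet, iterable of lesions, or lesion-table DataFrame
    into a list of :class:`LesionRecord`."""
    if isinstance(lesions, LesionSet):
        lesions = lesions.lesions
    if isinstance(lesions, pd.DataFrame):
        return [
            LesionRecord(int(r.lesion_id), float(r.suvmax), float(r.volume_ml))
            for r in lesions.itertuples()
        ]
    out = []
    for les in lesions:
        if isinstance(les, (Lesion, LesionRecord)):
            out.append(
                LesionRecord(int(les.lesion_id), float(les.suvmax), float(les.volume_ml))
            )
        else:  # (lesion_id, suvmax, volume_ml) triple
            out.append(LesionRecord(int(les[0]), float(les[1]), float(les[2])))
    return out


def select_top_k(lesions, k: int, criterion: str = "suvmax") -> list[LesionRecord]:
    """The k lesions with the largest criterion value.

    ``criterion`` is ``'suvmax'`` (hottest) or ``'volume'`` (largest).
    If fewer than k lesions exist, all are returned. Ties are broken by the
    deterministic lesion_id order (ascending), so the selection is
    reproducible on exact-tie inputs.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if criterion not in _CRITERIA:
        raise ValueError(f"criterion must be one of {_CRITERIA}, got {criterion!r}")
    records = as_records(lesions)
    key = (lambda r: (-r.suvmax, r.lesion_id)) if criterion == "suvmax" else (
        lambda r: (-r.volume_ml, r.lesion_id)
    )
    return sorted(records, key=key)[:k]


def summed_metric(lesions, metric: str = "suvmax") -> float:
    """Sum of a per-lesion metric; 0 for an empty set.

    ``metric`` is ``'suvmax'`` (summed SUVmax) or ``'volume_ml'`` (summed
    tumor volume in mL).
    """
    if metric not in ("suvmax", "volume_ml"):
        raise ValueError(f"metric must be 'suvmax' or 'volume_ml', got {metric!r}")
    records = as_records(lesions)
    if metric == "suvmax":
        return float(sum(r.suvmax for r in records))
    return float(sum(r.volume_ml for r in records))


def relative_change(baseline_sum: float, followup_sum: float) -> float:
    """Relative change in percent: followup/baseline * 100 - 100."""
    if baseline_sum <= 0:
        raise UndefinedBaselineError(
            f"relative change undefined for baseline sum {baseline_sum}"
        )
    return float(followup_sum) / float(baseline_sum) * 100.0 - 100.0


#: (metric family, subset) pairs computed for every patient. 'all' is the
#: whole-body sum, integers are top-k subsets, and ('suvmax', 1) is the
#: hottest lesion.
METRIC_KEYS = [
    ("suvmax", "all"),
    ("suvmax", 10),
    ("suvmax", 5),
    ("suvmax", 1),
    ("volume", "all"),
    ("volume", 10),
    ("volume", 5),
]


@dataclass(frozen=True)
class DeltaMetrics:
    """All summed metrics and relative changes for one patient.

    ``baseline_sums``, ``followup_sums`` and ``deltas`` are keyed by the
    (family, subset) pairs of :data:`METRIC_KEYS`; family 'suvmax' sums
    per-lesion SUVmax of the k hottest lesions, family 'volume' sums
    tumor volume (mL) of the k largest. deltas are percent.
    """

    baseline_sums: dict
    followup_sums: dict
    deltas: dict
    n_baseline: int
    n_followup: int

    # convenience accessors in the field's naming
    @property
    def delta_suvmax_all(self) -> float:
        return self.deltas[("suvmax", "all")]

    @property
    def delta_suvmax_10(self) -> float:
        return self.deltas[("suvmax", 10)]

    @property
    def delta_suvmax_5(self) -> float:
        return self.deltas[("suvmax", 5)]

    @property
    def delta_hottest(self) -> float:
        """Relative change of the single hottest lesion (top-1 SUVmax)."""
        return self.deltas[("suvmax", 1)]

    @property
    def delta_tv_all(self) -> float:
        return self.deltas[("volume", "all")]

    @property
    def delta_tv_10(self) -> float:
        return self.deltas[("volume", 10)]

    @property
    def delta_tv_5(self) -> float:
        return self.deltas[("volume", 5)]

    def as_row(self) -> dict:
        """Flat dict suitable for one CSV row."""
        row = {"n_lesions_baseline": self.n_baseline, "n_lesions_followup": self.n_followup}
        for family, subset in METRIC_KEYS:
            name = metric_name(family, subset)
            row[f"baseline_{name}"] = self.baseline_sums[(family, subset)]
            row[f"followup_{name}"] = self.followup_sums[(family, subset)]
            row[f"delta_{name}_pct"] = self.deltas[(family, subset)]
        return row


def metric_name(family: str, subset) -> str:
    base = "suvmax" if family == "suvmax" else "tv"
    if subset == "all":
        return f"{base}_all"
    if family == "suvmax" and subset == 1:
        return "hottest"
    return f"{base}_{subset}"


def patient_metrics(baseline, followup, ks: Sequence[int] = (10, 5)) -> DeltaMetrics:
    """Compute all summed metrics and relative changes for one patient.

    Top-k subsets are re-ranked independently per scan. A zero baseline sum
    raises :class:`UndefinedBaselineError` (a baseline scan with at least one
    lesion always has positive sums, so this only fires for lesion-free
    baselines).
    """
    bl = as_records(baseline)
    fu = as_records(followup)
    baseline_sums: dict = {}
    followup_sums: dict = {}
    deltas: dict = {}
    for family, subset in METRIC_KEYS:
        if subset not in ("all",) and subset not in ks and subset != 1:
            continue
        criterion = "suvmax" if family == "suvmax" else "volume"
        metric = "suvmax" if family == "suvmax" else "volume_ml"
        if subset == "all":
            sub_bl, sub_fu = bl, fu
        else:
            sub_bl = select_top_k(bl, subset, criterion)
            sub_fu = select_top_k(fu, subset, criterion)
        b = summed_metric(sub_bl, metric)
        f = summed_metric(sub_fu, metric)
        baseline_sums[(family, subset)] = b
        followup_sums[(family, subset)] = f
        deltas[(family, subset)] = relative_change(b, f)
    return DeltaMetrics(
        baseline_sums=baseline_sums,
        followup_sums=followup_sums,
        deltas=deltas,
        n_baseline=len(bl),
        n_followup=len(fu),
    )
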