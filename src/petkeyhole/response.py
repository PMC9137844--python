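"""Response classification and deviation grading.

A relative change of a summed metric is mapped to the three response
categories with the usual ±30% cut-offs:

* PD (progressive disease):   delta >= +30%
* PR (partial response):      delta <= -30%
* SD (stable disease):        -30% < delta < +30%

The boundary value +30 is classified PD (progression takes precedence) and
-30 is classified PR; classification uses the full-precision delta, with no
rounding (display rounding is a reporting concern only).

When a reduced (top-k) metric and the whole-body metric are classified
differently, the discrepancy is graded: a disagreement involving PD on one
side only would change patient management and is *clinically relevant*;
a PR-vs-SD disagreement is *non-relevant*; equal labels are *concordant*.
"""

from __future__ import annotations

from dataclasses import dataclass

from .exceptions import MetricFamilyError

__all__ = ["PD", "SD", "PR", "ResponseCall", "DeviationVerdict",
           "classify_response", "assess_deviation"]

PD = "PD"
SD = "SD"
PR = "PR"

_LABELS = (PD, SD, PR)
_VERDICTS = ("concordant", "non_relevant", "relevant")


@dataclass(frozen=True)
class ResponseCall:
    """A PD/SD/PR label together with the delta and metric it came from."""

    label: str
    delta_pct: float
    metric: str  # e.g. 'suvmax_all', 'tv_5', 'hottest'

    def __post_init__(self) -> None:
        if self.label not in _LABELS:
            raise ValueError(f"label must be one of {_LABELS}, got {self.label!r}")

    @property
    def family(self) -> str:
        """Metric family: 'suvmax' (incl. hottest) or 'tv'."""
        return "tv" if self.metric.startswith("tv") else "suvmax"


@dataclass(frozen=True)
class DeviationVerdict:
    """Concordance grading of a whole-body vs reduced-metric call pair."""

    verdict: str
    call_all: ResponseCall
    call_k: ResponseCall

    def __post_init__(self) -> None:
        if self.verdict not in _VERDICTS:
            raise ValueError(f"verdict must be one of {_VERDICTS}")


def classify_response(delta_pct: float, metric: str = "") -> ResponseCall:
    """Classify a relative change (percent) as PD, SD or PR."""
    d = float(delta_pct)
    if d >= 30.0:
        label = PD
    elif d <= -30.0:
        label = PR
    else:
        label = SD
    return ResponseCall(label=label, delta_pct=d, metric=metric)


def assess_deviation(call_all: ResponseCall, call_k: ResponseCall) -> DeviationVerdict:
    """Grade the discrepancy between a whole-body and a reduced-metric call.

    Symmetric in the two labels: relevant iff exactly one of the pair is PD,
    non-relevant for a PR/SD disagreement, concordant for equal labels.
    Both calls must come from the same metric family (SUVmax-type or
    tumor-volume-type).
    """
    if call_all.family != call_k.family:
        raise MetricFamilyError(
            f"cannot compare calls across metric families: "
            f"{call_all.metric!r} vs {call_k.metric!r}"
        )
    if call_all.label == call_k.label:
        verdict = "concordant"
    elif (call_all.label == PD) != (call_k.label == PD):
        verdict = "relevant"
    else:
        verdict = "non_relevant"
    return DeviationVerdict(verdict=verdict, call_all=call_all, call_k=call_k)
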