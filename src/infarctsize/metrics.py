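"""Per-section infarct percentages and per-heart aggregation.

Two standard planimetry scores:

* **area method** — 100 * (scar wall area) / (total LV wall area), the LV
  wall being viable + infarcted pixels (lumen, background and excluded
  regions enter neither term);
* **midline-length method** — 100 * (infarcted midline length) / (total
  midline length), the midline running halfway between the endocardial and
  epicardial surfaces.

The per-heart infarct size is the unweighted arithmetic mean over the
heart's (apex-to-base representative) sections.
"""

from __future__ import annotations

import logging

import numpy as np

from .errors import UndefinedScoreError, ValidationError
from .types import HeartResult, Label, LabelMask, MidlineTrace, SectionScores
from .midline import midline_lengths

__all__ = ["area_score", "midline_score", "aggregate_heart"]

log = logging.getLogger(__name__)


def area_score(mask: LabelMask) -> float:
    """Infarct percentage of the LV wall by pixel area."""
    counts = mask.counts()
    infarct = counts[Label.INFARCT]
    wall = infarct + counts[Label.VIABLE]
    if wall == 0:
        raise UndefinedScoreError("no wall pixels (viable or infarct) in mask")
    return 100.0 * infarct / wall


def midline_score(trace: MidlineTrace) -> float:
    """Infarct percentage of the LV wall by midline length."""
    total, infarct = midline_lengths(trace)
    if total <= 0:
        raise UndefinedScoreError("midline has zero total length")
    return 100.0 * infarct / total


def aggregate_heart(heart_id: str, scores: list[SectionScores]) -> HeartResult:
    """Unweighted per-heart mean of each method over all scored sections.

    Sections whose score is undefined for a method (``None``) are excluded
    from that method's mean and logged; 0% sections count normally.
    """
    if not scores:
        raise ValidationError(f"heart {heart_id!r}: no sections to aggregate")
    order = [s.order_index for s in scores]
    if len(set(order)) != len(order):
        raise ValidationError(f"heart {heart_id!r}: duplicate section order_index")
    ordered = sorted(scores, key=lambda s: s.order_index)

    def _mean(values: list[float | None], method: str) -> float | None:
        defined = [v for v in values if v is not None]
        if len(defined) < len(values):
            log.warning(
                "heart %s: %d section(s) undefined for %s method, dropped from mean",
                heart_id,
                len(values) - len(defined),
                method,
            )
        if not defined:
            return None
        return float(np.mean(defined))

    return HeartResult(
        heart_id=heart_id,
        sections=ordered,
        mean_area_pct=_mean([s.area_pct for s in ordered], "area"),
        mean_midline_pct=_mean([s.midline_pct for s in ordered], "midline"),
    )
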