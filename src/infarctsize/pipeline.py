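"""Batch driver: segment -> trace -> score, per section and per heart."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .errors import GeometryError, UndefinedScoreError
from .metrics import aggregate_heart, area_score, midline_score
from .midline import DEFAULT_N_RAYS, DEFAULT_SMOOTH_DEG, DEFAULT_STEP, cast_rays, lumen_centre
from .segmentation import DEFAULT_TOLERANCE, segment_section
from .types import HeartResult, LabelMask, MidlineTrace, SectionImage, SectionScores, SeedSet
from .io import MEAN_ROW_ID

__all__ = ["SectionResult", "quantify_section", "quantify_heart", "results_table"]

log = logging.getLogger(__name__)

#: A section is flagged when fewer than this fraction of rays cross the wall.
_FEW_RAYS_FRACTION = 0.5


@dataclass
class SectionResult:
    """Scores plus the intermediate artefacts of one section."""

    scores: SectionScores
    mask: LabelMask
    trace: Optional[MidlineTrace]


def quantify_section(
    image: SectionImage,
    seeds: Optional[SeedSet] = None,
    tolerance: float = DEFAULT_TOLERANCE,
    n_rays: int = DEFAULT_N_RAYS,
    step: float = DEFAULT_STEP,
    smooth: bool = True,
    smooth_deg: float = DEFAULT_SMOOTH_DEG,
) -> SectionResult:
    """Run the full pipeline on one section.

    Scores that are undefined for this section (no wall pixels; fewer than
    two rays crossing the wall) come back as ``None`` with a flag instead of
    raising, so one bad section cannot abort a batch.
    """
    mask = segment_section(image, seeds, tolerance=tolerance, smooth=smooth)
    flags: set[str] = set()

    try:
        area = area_score(mask)
    except UndefinedScoreError:
        area = None
        flags.add("no_wall")

    trace = None
    mid = None
    try:
        centre, fallback = lumen_centre(mask)
        if fallback:
            flags.add("no_lumen_fallback")
        trace = cast_rays(
            mask,
            centre,
            n_rays=n_rays,
            step=step,
            smooth_deg=smooth_deg,
            used_fallback_centre=fallback,
        )
        if trace.n_valid < _FEW_RAYS_FRACTION * n_rays:
            flags.add("few_valid_rays")
        mid = midline_score(trace)
    except (GeometryError, UndefinedScoreError) as exc:
        flags.add("few_valid_rays")
        log.warning("section %s: midline undefined (%s)", image.section_id, exc)

    scores = SectionScores(
        section_id=image.section_id,
        area_pct=area,
        midline_pct=mid,
        flags=flags,
        order_index=image.order_index,
    )
    return SectionResult(scores=scores, mask=mask, trace=trace)


def quantify_heart(
    heart_id: str,
    sections: Iterable[tuple[SectionImage, Optional[SeedSet]]],
    **kwargs,
) -> tuple[HeartResult, list[SectionResult]]:
    """Quantify every section of one heart and aggregate the means."""
    results = [quantify_section(img, seeds, **kwargs) for img, seeds in sections]
    heart = aggregate_heart(heart_id, [r.scores for r in results])
    return heart, results


def results_table(hearts: Iterable[HeartResult]) -> pd.DataFrame:
    """Tabulate per-section rows plus one MEAN summary row per heart.

    Rows are sorted by ``(heart_id, order_index)`` regardless of input
    order; each heart's summary row follows its sections.
    """
    rows = []
    for heart in sorted(hearts, key=lambda h: h.heart_id):
        for s in sorted(heart.sections, key=lambda s: s.order_index):
            rows.append(
                {
                    "heart_id": heart.heart_id,
                    "section_id": s.section_id,
                    "area_pct": np.nan if s.area_pct is None else s.area_pct,
                    "midline_pct": np.nan if s.midline_pct is None else s.midline_pct,
                }
            )
        rows.append(
            {
                "heart_id": heart.heart_id,
                "section_id": MEAN_ROW_ID,
                "area_pct": np.nan if heart.mean_area_pct is None else heart.mean_area_pct,
                "midline_pct": np.nan
                if heart.mean_midline_pct is None
                else heart.mean_midline_pct,
            }
        )
    return pd.DataFrame(rows, columns=["heart_id", "section_id", "area_pct", "midline_pct"])
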