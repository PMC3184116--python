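"""Domain containers shared by all modules.

Conventions used throughout the package:

* pixel coordinates are 0-based ``(row, col)`` with row 0 at the image top;
* label maps use the integer codes of :class:`Label`;
* percentages are on the 0–100 scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Optional, Sequence

import numpy as np

from .errors import ValidationError

__all__ = [
    "Label",
    "SectionImage",
    "SeedSet",
    "LabelMask",
    "MidlineTrace",
    "SectionScores",
    "HeartResult",
    "AgreementResult",
]


class Label(IntEnum):
    """Per-pixel tissue classes. Values are the on-disk PNG codes."""

    BACKGROUND = 0
    LUMEN = 1
    VIABLE = 2
    INFARCT = 3
    EXCLUDED = 4


@dataclass
class SectionImage:
    """One RGB photograph of a transverse heart section.

    Parameters
    ----------
    pixels
        ``H x W x 3`` uint8 array, exactly as decoded from disk.
    section_id
        Identifier of the section (unique within a heart).
    order_index
        Apex-to-base position of the section within its heart.
    pixel_size_um
        Physical pixel pitch in micrometres, if known. Both infarct scores
        are ratios, so this is informational only.
    """

    pixels: np.ndarray
    section_id: str
    order_index: int = 0
    pixel_size_um: Optional[float] = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValidationError(
                f"section {self.section_id!r}: expected H x W x 3 pixels, "
                f"got shape {px.shape}"
            )
        if px.shape[0] < 16 or px.shape[1] < 16:
            raise ValidationError(
                f"section {self.section_id!r}: image {px.shape[0]}x{px.shape[1]} "
                "is smaller than the 16x16 minimum"
            )
        if px.dtype != np.uint8:
            raise ValidationError(
                f"section {self.section_id!r}: pixels must be uint8, got {px.dtype}"
            )
        if self.pixel_size_um is not None and self.pixel_size_um <= 0:
            raise ValidationError("pixel_size_um must be positive")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


def _as_polygon(vertices: Sequence) -> np.ndarray:
    poly = np.asarray(vertices, dtype=float)
    if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
        raise ValidationError(
            f"exclusion polygon needs >= 3 (row, col) vertices, got {poly.shape}"
        )
    return poly


@dataclass
class SeedSet:
    """User-chosen seed pixels and exclusion regions for one section.

    ``lumen_seeds`` and ``viable_seeds`` replace the interactive clicks of a
    GUI; either list may be empty ("if present in the image").
    """

    lumen_seeds: list[tuple[int, int]] = field(default_factory=list)
    viable_seeds: list[tuple[int, int]] = field(default_factory=list)
    exclusion_polygons: list[np.ndarray] = field(default_factory=list)
    tolerance_override: Optional[float] = None

    def __post_init__(self) -> None:
        self.lumen_seeds = [(int(r), int(c)) for r, c in self.lumen_seeds]
        self.viable_seeds = [(int(r), int(c)) for r, c in self.viable_seeds]
        if set(self.lumen_seeds) & set(self.viable_seeds):
            raise ValidationError("lumen and viable seed lists overlap")
        if self.tolerance_override is not None and self.tolerance_override <= 0:
            raise ValidationError("tolerance_override must be positive")
        self.exclusion_polygons = [_as_polygon(p) for p in self.exclusion_polygons]

    @classmethod
    def empty(cls) -> "SeedSet":
        return cls()

    def validate_bounds(self, shape: tuple[int, int], section_id: str = "?") -> None:
        """Raise if any seed or polygon vertex lies outside ``shape``."""
        h, w = shape
        for name, seeds in (("lumen", self.lumen_seeds), ("viable", self.viable_seeds)):
            for r, c in seeds:
                if not (0 <= r < h and 0 <= c < w):
                    raise ValidationError(
                        f"section {section_id!r}: {name} seed ({r}, {c}) outside "
                        f"{h}x{w} image"
                    )
        for poly in self.exclusion_polygons:
            if (
                poly[:, 0].min() < 0
                or poly[:, 1].min() < 0
                or poly[:, 0].max() >= h
                or poly[:, 1].max() >= w
            ):
                raise ValidationError(
                    f"section {section_id!r}: exclusion polygon vertex outside "
                    f"{h}x{w} image"
                )


@dataclass
class LabelMask:
    """Per-pixel tissue class map over :class:`Label`.

    The five classes partition the image: every pixel carries exactly one
    label.
    """

    labels: np.ndarray
    tolerance_used: Optional[float] = None
    connectivity: int = 8

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValidationError(f"label map must be 2-D, got shape {lab.shape}")
        if self.connectivity not in (4, 8):
            raise ValidationError("connectivity must be 4 or 8")
        lab = lab.astype(np.uint8, copy=False)
        if lab.size and lab.max() > max(Label):
            raise ValidationError("label map contains codes outside the Label enum")
        self.labels = lab

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def mask(self, label: Label) -> np.ndarray:
        return self.labels == int(label)

    def counts(self) -> dict[Label, int]:
        binc = np.bincount(self.labels.ravel(), minlength=len(Label))
        return {lab: int(binc[int(lab)]) for lab in Label}


@dataclass
class MidlineTrace:
    """Radial midline trace around the lumen centre.

    All per-ray arrays have length ``n_rays``; invalid rays (no wall crossed)
    carry NaN geometry and ``valid == False``.
    """

    theta: np.ndarray           # radians in [0, 2pi), strictly increasing
    endo_radius: np.ndarray     # px, first wall crossing (after smoothing)
    epi_radius: np.ndarray      # px, outer end of the first wall run
    midline_points: np.ndarray  # (n_rays, 2) continuous (row, col)
    wall_thickness: np.ndarray  # px, epi - endo
    infarct_fraction: np.ndarray  # raw infarct/tissue sample ratio in [0, 1]
    infarcted: np.ndarray       # bool, transmurality call (> 50% rule)
    valid: np.ndarray           # bool
    centre: tuple[float, float]
    used_fallback_centre: bool = False

    @property
    def n_rays(self) -> int:
        return int(self.theta.size)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


@dataclass
class SectionScores:
    """Infarct percentages of one section by both methods.

    A score is ``None`` when its denominator is undefined for this section
    (no wall pixels, or fewer than two valid rays); such sections are dropped
    from per-heart means and flagged.
    """

    section_id: str
    area_pct: Optional[float]
    midline_pct: Optional[float]
    flags: set[str] = field(default_factory=set)
    order_index: int = 0


@dataclass
class HeartResult:
    """Per-heart aggregate: unweighted means over its scored sections."""

    heart_id: str
    sections: list[SectionScores]
    mean_area_pct: Optional[float]
    mean_midline_pct: Optional[float]


@dataclass
class AgreementResult:
    """Bland-Altman agreement between two methods measuring the same quantity.

    ``loa_low``/``loa_high`` are ``bias -/+ 1.96 * sd_diff``. Confidence
    intervals are ``None`` when n < 3.
    """

    n: int
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    ci_bias: Optional[tuple[float, float]] = None
    ci_loa_low: Optional[tuple[float, float]] = None
    ci_loa_high: Optional[tuple[float, float]] = None
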