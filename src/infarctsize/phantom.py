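"""Synthetic MT-like section phantoms with known infarct geometry.

A phantom is an annular LV wall around a pale lumen on a pale slide
background: collagen-blue scar in an angular sector, muscle-red viable
tissue elsewhere. The wall may be thinned inside the scar sector (chronic
infarcts thin the wall) and the scar may be limited to the outer fraction of
the wall thickness (non-transmural injury). Because the geometry is closed
form, the true infarct percentages are known exactly and every stage of the
pipeline can be tested without histology data.

Rendering is bit-reproducible: the class map is computed analytically from
pixel-centre radii/angles and i.i.d. Gaussian noise is added from a seeded
generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np

from .errors import ValidationError
from .types import Label, LabelMask, SectionImage, SeedSet

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "render_phantom",
    "render_heart_series",
    "closed_form_area_pct",
]

#: Default class colours, approximating a Masson's trichrome stain:
#: muscle red, collagen blue, pale lumen/slide.
VIABLE_RGB = (170, 60, 70)
INFARCT_RGB = (70, 90, 200)
LUMEN_RGB = (245, 245, 245)
BACKGROUND_RGB = (245, 245, 245)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, colours and noise of one synthetic section.

    ``infarct_sector`` is ``(theta0, theta1)`` in radians with
    ``0 <= theta1 - theta0 <= 2*pi`` (angles measured from the +col axis
    towards the +row axis). ``thinning`` scales the wall thickness inside
    the sector; ``transmural_depth`` limits the scar to the outer fraction
    of the (possibly thinned) wall.
    """

    image_size: tuple[int, int] = (512, 512)
    centre: Optional[tuple[float, float]] = None
    endo_radius: float = 150.0
    epi_radius: float = 180.0
    infarct_sector: tuple[float, float] = (0.0, 0.0)
    thinning: float = 1.0
    transmural_depth: float = 1.0
    viable_rgb: tuple[int, int, int] = VIABLE_RGB
    infarct_rgb: tuple[int, int, int] = INFARCT_RGB
    lumen_rgb: tuple[int, int, int] = LUMEN_RGB
    background_rgb: tuple[int, int, int] = BACKGROUND_RGB
    noise_sigma: float = 4.0
    rng_seed: int = 0
    decoy_blob: Optional[tuple[tuple[float, float], float]] = None

    def __post_init__(self) -> None:
        h, w = self.image_size
        if h < 16 or w < 16:
            raise ValidationError("image_size must be at least 16x16")
        if not (0 < self.endo_radius < self.epi_radius < min(h, w) / 2):
            raise ValidationError(
                "need 0 < endo_radius < epi_radius < min(image_size)/2"
            )
        t0, t1 = self.infarct_sector
        if not (0.0 <= t1 - t0 <= 2 * np.pi + 1e-12):
            raise ValidationError("infarct sector width must be in [0, 2*pi]")
        if not (0 < self.thinning <= 1):
            raise ValidationError("thinning must be in (0, 1]")
        if not (0 < self.transmural_depth <= 1):
            raise ValidationError("transmural_depth must be in (0, 1]")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        # Ground truth must be recoverable from colour: every class pair
        # except lumen/background (distinguished by enclosure, not colour)
        # has to sit >= 5 sigma apart in RGB.
        pairs = [
            (self.viable_rgb, self.infarct_rgb),
            (self.viable_rgb, self.lumen_rgb),
            (self.viable_rgb, self.background_rgb),
            (self.infarct_rgb, self.lumen_rgb),
            (self.infarct_rgb, self.background_rgb),
        ]
        for a, b in pairs:
            dist = float(np.linalg.norm(np.subtract(a, b, dtype=float)))
            if dist < 5 * self.noise_sigma:
                raise ValidationError(
                    f"colours {a} and {b} are only {dist:.1f} apart; need >= "
                    f"5*noise_sigma = {5 * self.noise_sigma:.1f}"
                )
        if self.decoy_blob is not None:
            (br, bc), rad = self.decoy_blob
            cr, cc = self._centre()
            if np.hypot(br - cr, bc - cc) - rad <= self.epi_radius:
                raise ValidationError("decoy blob overlaps the LV wall")

    def _centre(self) -> tuple[float, float]:
        if self.centre is not None:
            return float(self.centre[0]), float(self.centre[1])
        return self.image_size[0] / 2.0, self.image_size[1] / 2.0

    @property
    def sector_width(self) -> float:
        return self.infarct_sector[1] - self.infarct_sector[0]


@dataclass
class PhantomTruth:
    """Noiseless ground truth of one phantom."""

    mask: LabelMask
    true_area_pct: float
    true_midline_pct: float
    transmural: bool
    lumen_centre: tuple[float, float]


def closed_form_area_pct(spec: PhantomSpec) -> float:
    """Analytic area-method percentage for a fully transmural sector.

    With sector fraction f, endo radius a, epi radius b and thinned sector
    outer radius b' = a + thinning*(b - a):

        100 * f*(b'^2 - a^2) / (f*(b'^2 - a^2) + (1 - f)*(b^2 - a^2))
    """
    f = spec.sector_width / (2 * np.pi)
    a = spec.endo_radius
    b = spec.epi_radius
    bp = a + spec.thinning * (b - a)
    num = f * (bp**2 - a**2)
    den = num + (1 - f) * (b**2 - a**2)
    if den == 0:
        return 0.0
    return 100.0 * num / den


def _truth_labels(spec: PhantomSpec) -> np.ndarray:
    h, w = spec.image_size
    cr, cc = spec._centre()
    rows, cols = np.mgrid[0:h, 0:w]
    dr = rows - cr
    dc = cols - cc
    radius = np.hypot(dr, dc)
    angle = np.mod(np.arctan2(dr, dc), 2 * np.pi)

    width = spec.sector_width
    t0 = spec.infarct_sector[0]
    if width >= 2 * np.pi - 1e-12:
        in_sector = np.ones((h, w), bool)
    elif width <= 0:
        in_sector = np.zeros((h, w), bool)
    else:
        in_sector = np.mod(angle - t0, 2 * np.pi) < width

    a = spec.endo_radius
    b = spec.epi_radius
    bp = a + spec.thinning * (b - a)
    outer = np.where(in_sector, bp, b)

    labels = np.full((h, w), int(Label.BACKGROUND), np.uint8)
    labels[radius < a] = int(Label.LUMEN)
    wall = (radius >= a) & (radius <= outer)
    labels[wall] = int(Label.VIABLE)
    depth_r = bp - spec.transmural_depth * (bp - a)
    labels[wall & in_sector & (radius >= depth_r)] = int(Label.INFARCT)

    if spec.decoy_blob is not None:
        (br, bc), rad = spec.decoy_blob
        blob = np.hypot(rows - br, cols - bc) <= rad
        # decoy tissue is not LV: truth-labelled EXCLUDED so it never enters
        # the true percentages
        labels[blob & (labels == int(Label.BACKGROUND))] = int(Label.EXCLUDED)
    return labels


def _viable_seed(spec: PhantomSpec, labels: np.ndarray) -> Optional[tuple[int, int]]:
    if not (labels == int(Label.VIABLE)).any():
        return None
    cr, cc = spec._centre()
    t0, t1 = spec.infarct_sector
    theta = np.mod(0.5 * (t0 + t1) + np.pi, 2 * np.pi)
    r = 0.5 * (spec.endo_radius + spec.epi_radius)
    seed = (int(round(cr + r * np.sin(theta))), int(round(cc + r * np.cos(theta))))
    if labels[seed] == int(Label.VIABLE):
        return seed
    rows, cols = np.nonzero(labels == int(Label.VIABLE))
    k = int(np.argmin((rows - seed[0]) ** 2 + (cols - seed[1]) ** 2))
    return int(rows[k]), int(cols[k])


def render_phantom(
    spec: PhantomSpec, section_id: str = "phantom", order_index: int = 0
) -> tuple[SectionImage, PhantomTruth, SeedSet]:
    """Render one phantom: noisy image, noiseless truth and a seed set.

    The seed set holds one lumen seed at the centre and one viable seed at
    mid-wall opposite the scar sector (absent when the respective class is
    empty).
    """
    labels = _truth_labels(spec)
    h, w = spec.image_size
    palette = np.array(
        [
            spec.background_rgb,
            spec.lumen_rgb,
            spec.viable_rgb,
            spec.infarct_rgb,
            spec.viable_rgb,  # EXCLUDED truth code renders as decoy tissue
        ],
        dtype=float,
    )
    base = palette[labels]
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.rng_seed)
        base = base + rng.normal(0.0, spec.noise_sigma, base.shape)
    pixels = np.clip(np.rint(base), 0, 255).astype(np.uint8)

    counts = np.bincount(labels.ravel(), minlength=len(Label))
    infarct = int(counts[int(Label.INFARCT)])
    wall = infarct + int(counts[int(Label.VIABLE)])
    true_area = 100.0 * infarct / wall if wall else 0.0
    transmural = spec.transmural_depth > 0.5
    width = spec.sector_width
    true_midline = 100.0 * width / (2 * np.pi) if (transmural and width > 0) else 0.0

    cr, cc = spec._centre()
    lumen_seed = (int(round(cr)), int(round(cc)))
    seeds = SeedSet(
        lumen_seeds=[lumen_seed] if labels[lumen_seed] == int(Label.LUMEN) else [],
        viable_seeds=[s for s in [_viable_seed(spec, labels)] if s is not None],
    )
    truth = PhantomTruth(
        mask=LabelMask(labels=labels, tolerance_used=None, connectivity=8),
        true_area_pct=true_area,
        true_midline_pct=true_midline,
        transmural=transmural,
        lumen_centre=(cr, cc),
    )
    image = SectionImage(pixels=pixels, section_id=section_id, order_index=order_index)
    return image, truth, seeds


def render_heart_series(
    base_spec: PhantomSpec,
    n_sections: int,
    profile: Sequence[Union[float, tuple[float, float]]],
    heart_id: str = "heart",
) -> list[tuple[SectionImage, PhantomTruth, SeedSet]]:
    """Render an apex-to-base series of phantom sections for one heart.

    ``profile`` gives one scar sector per section, either as a width in
    radians (sector starts at the base spec's theta0) or as an explicit
    ``(theta0, theta1)`` pair. Section k is rendered with
    ``rng_seed = base_spec.rng_seed + k`` so the series is deterministic but
    not pixel-identical across sections.
    """
    if len(profile) != n_sections:
        raise ValidationError(
            f"profile length {len(profile)} != n_sections {n_sections}"
        )
    out = []
    for k, entry in enumerate(profile):
        if isinstance(entry, (tuple, list)):
            sector = (float(entry[0]), float(entry[1]))
        else:
            t0 = base_spec.infarct_sector[0]
            sector = (t0, t0 + float(entry))
        spec = replace(base_spec, infarct_sector=sector, rng_seed=base_spec.rng_seed + k)
        out.append(
            render_phantom(spec, section_id=f"{heart_id}_s{k + 1:02d}", order_index=k)
        )
    return out
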