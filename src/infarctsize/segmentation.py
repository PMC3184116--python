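"""Pixel classification of a section into tissue classes.

The classifier is deliberately simple and fully deterministic:

* the slide background is every "pale" pixel reachable from the image border
  (flood fill), so pale blood trapped inside the lumen is *not* background;
* the left-ventricle lumen and the viable (muscle-red) myocardium are grown
  from user seeds by seeded region growing with a running-mean colour
  homogeneity criterion;
* scar is never seeded — the ischemic tissue is too heterogeneous — and is
  assigned by exclusion: whatever tissue remains is infarct.

Region growing is breadth-first with neighbours visited in row-major order
and the region mean updated as each pixel joins, which makes the result
reproducible bit for bit.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence, Union

import numpy as np
from numba import njit
from scipy import ndimage
from skimage.draw import polygon as _draw_polygon

from .errors import ValidationError
from .types import Label, LabelMask, SectionImage, SeedSet

__all__ = [
    "DEFAULT_TOLERANCE",
    "DEFAULT_WHITENESS",
    "detect_background",
    "region_grow",
    "segment_section",
    "apply_exclusion",
    "rasterize_polygon",
]

log = logging.getLogger(__name__)

#: Default colour-homogeneity tolerance (Euclidean RGB distance to the
#: running region mean). User-adjustable; the useful range for MT-stained
#: sections is roughly 30-120.
DEFAULT_TOLERANCE = 60.0

#: A pixel is "pale" when all three channels are at least this bright.
DEFAULT_WHITENESS = 220

_NB8 = np.array(
    [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)],
    dtype=np.int64,
)
_NB4 = np.array([(-1, 0), (0, -1), (0, 1), (1, 0)], dtype=np.int64)

_STATE_FREE = 0
_STATE_IN = 1
_STATE_FORBIDDEN = 2


@njit(cache=True)
def _grow_kernel(img, state, seed_rows, seed_cols, tol2, offsets):  # pragma: no cover
    h, w = state.shape
    qr = np.empty(h * w, np.int64)
    qc = np.empty(h * w, np.int64)
    head = 0
    tail = 0
    sr = 0.0
    sg = 0.0
    sb = 0.0
    cnt = 0.0
    for k in range(seed_rows.size):
        r = seed_rows[k]
        c = seed_cols[k]
        if state[r, c] == 1:
            continue
        state[r, c] = 1
        sr += img[r, c, 0]
        sg += img[r, c, 1]
        sb += img[r, c, 2]
        cnt += 1.0
        qr[tail] = r
        qc[tail] = c
        tail += 1
    while head < tail:
        r = qr[head]
        c = qc[head]
        head += 1
        for k in range(offsets.shape[0]):
            rr = r + offsets[k, 0]
            cc = c + offsets[k, 1]
            if rr < 0 or rr >= h or cc < 0 or cc >= w:
                continue
            if state[rr, cc] != 0:
                continue
            mr = sr / cnt
            mg = sg / cnt
            mb = sb / cnt
            dr = img[rr, cc, 0] - mr
            dg = img[rr, cc, 1] - mg
            db = img[rr, cc, 2] - mb
            if dr * dr + dg * dg + db * db <= tol2:
                state[rr, cc] = 1
                sr += img[rr, cc, 0]
                sg += img[rr, cc, 1]
                sb += img[rr, cc, 2]
                cnt += 1.0
                qr[tail] = rr
                qc[tail] = cc
                tail += 1


def _pixels(image: Union[SectionImage, np.ndarray]) -> np.ndarray:
    if isinstance(image, SectionImage):
        return image.pixels
    px = np.asarray(image)
    if px.ndim != 3 or px.shape[2] != 3:
        raise ValidationError(f"expected an H x W x 3 image, got shape {px.shape}")
    return px


def detect_background(
    image: Union[SectionImage, np.ndarray],
    whiteness: int = DEFAULT_WHITENESS,
    connectivity: int = 4,
    blocked: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Mask of pale pixels reachable from the image border.

    The unstained slide around the section is bright in all channels; flood
    filling from the border keeps pale pixels *enclosed* by tissue (lumen,
    intramural blood) out of the background. 4-connectivity by default so the
    fill cannot leak diagonally through one-pixel tissue gaps.

    Parameters
    ----------
    blocked
        Optional boolean mask of pixels the fill may never enter (used for
        exclusion regions).
    """
    px = _pixels(image)
    pale = px.min(axis=2) >= whiteness
    if blocked is not None:
        pale &= ~blocked
    if connectivity == 4:
        structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool)
    elif connectivity == 8:
        structure = np.ones((3, 3), bool)
    else:
        raise ValidationError("connectivity must be 4 or 8")
    labelled, _ = ndimage.label(pale, structure=structure)
    border = np.concatenate(
        [labelled[0, :], labelled[-1, :], labelled[:, 0], labelled[:, -1]]
    )
    reach = np.unique(border[border > 0])
    if reach.size == 0:
        return np.zeros(pale.shape, bool)
    return np.isin(labelled, reach)


def region_grow(
    image: Union[SectionImage, np.ndarray],
    seeds: Sequence[tuple[int, int]],
    tolerance: float = DEFAULT_TOLERANCE,
    forbidden: Optional[np.ndarray] = None,
    connectivity: int = 8,
) -> np.ndarray:
    """Seeded region growing with a running-mean colour criterion.

    A candidate pixel joins the region when the Euclidean RGB distance
    between its colour and the current mean colour of the region is at most
    ``tolerance``. Expansion is breadth-first from the seeds (in the given
    order) with neighbours tested in row-major order; the mean is updated as
    each pixel joins and an accepted pixel is never re-tested. A pixel
    rejected at one moment may join later through another neighbour once the
    mean has drifted towards it.

    Returns the boolean region mask.
    """
    px = _pixels(image)
    h, w = px.shape[:2]
    if tolerance <= 0:
        raise ValidationError("tolerance must be positive")
    if connectivity not in (4, 8):
        raise ValidationError("connectivity must be 4 or 8")
    seeds = [(int(r), int(c)) for r, c in seeds]
    if not seeds:
        raise ValidationError("region_grow needs at least one seed")
    state = np.zeros((h, w), np.int8)
    if forbidden is not None:
        forbidden = np.asarray(forbidden, bool)
        if forbidden.shape != (h, w):
            raise ValidationError("forbidden mask shape does not match the image")
        state[forbidden] = _STATE_FORBIDDEN
    for r, c in seeds:
        if not (0 <= r < h and 0 <= c < w):
            raise ValidationError(f"seed ({r}, {c}) outside {h}x{w} image")
        if state[r, c] == _STATE_FORBIDDEN:
            raise ValidationError(f"seed ({r}, {c}) lies in a forbidden region")
    offsets = _NB8 if connectivity == 8 else _NB4
    _grow_kernel(
        px.astype(np.float64),
        state,
        np.array([s[0] for s in seeds], np.int64),
        np.array([s[1] for s in seeds], np.int64),
        float(tolerance) * float(tolerance),
        offsets,
    )
    return state == _STATE_IN


def rasterize_polygon(poly: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of the pixels inside a closed (row, col) polygon."""
    poly = np.asarray(poly, float)
    if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
        raise ValidationError(
            f"polygon needs >= 3 (row, col) vertices, got shape {poly.shape}"
        )
    rr, cc = _draw_polygon(poly[:, 0], poly[:, 1], shape)
    mask = np.zeros(shape, bool)
    mask[rr, cc] = True
    return mask


def _smooth_rgb(px: np.ndarray) -> np.ndarray:
    # 3x3 median per channel: suppresses JPEG/sensor speckle without
    # blending colours across class boundaries (a median keeps the majority
    # side's value at a hard edge).
    return ndimage.median_filter(px, size=(3, 3, 1))


def segment_section(
    image: Union[SectionImage, np.ndarray],
    seeds: Optional[SeedSet] = None,
    tolerance: float = DEFAULT_TOLERANCE,
    smooth: bool = True,
    whiteness: int = DEFAULT_WHITENESS,
) -> LabelMask:
    """Classify every pixel of a section.

    Pipeline, in precedence order:

    1. EXCLUDED — pixels inside the seed set's exclusion polygons;
    2. BACKGROUND — pale pixels reachable from the border (flood fill on the
       remainder);
    3. LUMEN — grown from the lumen seeds (empty seed list => no lumen);
    4. VIABLE — grown from the viable seeds, never entering lumen;
    5. INFARCT — every remaining non-background, non-excluded pixel.

    ``seeds.tolerance_override`` wins over ``tolerance`` when set.
    """
    px = _pixels(image)
    section_id = image.section_id if isinstance(image, SectionImage) else "?"
    if seeds is None:
        seeds = SeedSet.empty()
    seeds.validate_bounds(px.shape[:2], section_id)
    tol = seeds.tolerance_override if seeds.tolerance_override else tolerance
    if tol <= 0:
        raise ValidationError("tolerance must be positive")

    work = _smooth_rgb(px) if smooth else px

    excluded = np.zeros(px.shape[:2], bool)
    for poly in seeds.exclusion_polygons:
        excluded |= rasterize_polygon(poly, px.shape[:2])

    background = detect_background(work, whiteness=whiteness, blocked=excluded)

    if seeds.lumen_seeds:
        lumen = region_grow(work, seeds.lumen_seeds, tol, forbidden=excluded | background)
    else:
        lumen = np.zeros(px.shape[:2], bool)

    if seeds.viable_seeds:
        viable = region_grow(
            work, seeds.viable_seeds, tol, forbidden=excluded | background | lumen
        )
    else:
        viable = np.zeros(px.shape[:2], bool)

    labels = np.full(px.shape[:2], int(Label.INFARCT), np.uint8)
    labels[background] = int(Label.BACKGROUND)
    labels[lumen] = int(Label.LUMEN)
    labels[viable] = int(Label.VIABLE)
    labels[excluded] = int(Label.EXCLUDED)
    return LabelMask(labels=labels, tolerance_used=float(tol), connectivity=8)


def apply_exclusion(mask: LabelMask, polygon: np.ndarray) -> LabelMask:
    """Return a copy of ``mask`` with the polygon interior set to EXCLUDED.

    Used to remove tissue that is not left ventricle (right-ventricle wall,
    blood in the lumen, debris) after an initial segmentation. Idempotent.
    """
    region = rasterize_polygon(np.asarray(polygon, float), mask.shape)
    labels = mask.labels.copy()
    labels[region] = int(Label.EXCLUDED)
    return LabelMask(
        labels=labels, tolerance_used=mask.tolerance_used, connectivity=mask.connectivity
    )
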