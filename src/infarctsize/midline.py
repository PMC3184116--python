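"""Radial midline tracing of the left-ventricle wall.

Rays are cast from the lumen centre at equally spaced angles. Along each ray
the first contiguous run of wall tissue defines the endocardial and
epicardial crossings; the midline point sits halfway between them. A ray is
called *infarcted* when scar occupies more than half of the wall's radial
thickness there (the midline of the scarred region only counts where the
wall is affected in more than 50% of its thickness).

Angle convention: ``theta`` is measured from the +col axis towards the +row
axis, i.e. the ray direction is ``(d_row, d_col) = (sin theta, cos theta)``.
"""

from __future__ import annotations

from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import GeometryError, ValidationError
from .types import Label, LabelMask, MidlineTrace

__all__ = [
    "DEFAULT_N_RAYS",
    "lumen_centre",
    "cast_rays",
    "midline_lengths",
    "apply_ray_overrides",
    "trace_to_frame",
]

DEFAULT_N_RAYS = 360

#: Sampling step along a ray, in pixels. Sub-pixel stepping bounds the
#: quantisation error on thin walls.
DEFAULT_STEP = 0.5

#: Angular width (degrees) of the circular moving average applied to the
#: per-ray endo/epi radii. The raw radii zig-zag at the +-0.5 px pixel scale;
#: without denoising the zig-zag inflates the midline polygon length and
#: makes it depend on the ray count. 0 disables smoothing.
DEFAULT_SMOOTH_DEG = 3.0

#: The transmurality call requires the infarct's radial extent to exceed
#: half the wall thickness by more than this many pixels. Nearest-neighbour
#: lookups on a rasterised mask localise each of the three run boundaries
#: (endo, viable/infarct transition, epi) only to ~0.5 px, with a
#: *systematic* bias at lattice-aligned angles, so a smaller majority is
#: below the measurement resolution. See docs/methods.md.
_TRANSMURAL_GUARD_PX = 1.5


def lumen_centre(mask: LabelMask) -> tuple[tuple[float, float], bool]:
    """Centroid of the lumen, or of the wall when the lumen is obliterated.

    Sections near the apex may show no lumen; the centroid of the wall
    (viable + infarct) is then used and flagged.

    Returns ``((row, col), used_fallback)``.
    """
    lum = mask.mask(Label.LUMEN)
    if lum.any():
        rows, cols = np.nonzero(lum)
        return (float(rows.mean()), float(cols.mean())), False
    wall = mask.mask(Label.VIABLE) | mask.mask(Label.INFARCT)
    if wall.any():
        rows, cols = np.nonzero(wall)
        return (float(rows.mean()), float(cols.mean())), True
    raise GeometryError("mask contains no lumen and no wall tissue")


def _circular_smooth(values: np.ndarray, valid: np.ndarray, window: int) -> np.ndarray:
    """NaN-aware circular moving average; invalid rays stay NaN."""
    if window <= 1:
        return values
    filled = np.where(valid, values, 0.0)
    weight = valid.astype(float)
    kernel = np.ones(window)
    num = ndimage.convolve1d(filled, kernel, mode="wrap")
    den = ndimage.convolve1d(weight, kernel, mode="wrap")
    out = np.full_like(values, np.nan)
    ok = valid & (den > 0)
    out[ok] = num[ok] / den[ok]
    return out


def cast_rays(
    mask: LabelMask,
    centre: tuple[float, float],
    n_rays: int = DEFAULT_N_RAYS,
    step: float = DEFAULT_STEP,
    smooth_deg: float = DEFAULT_SMOOTH_DEG,
    used_fallback_centre: bool = False,
) -> MidlineTrace:
    """Trace ``n_rays`` equally spaced rays from ``centre`` outwards.

    Per ray: samples the label map every ``step`` px (nearest-neighbour
    lookup); the endocardial radius is the first sample inside the wall, the
    epicardial radius the last sample of that first contiguous wall run
    (EXCLUDED samples do not break the run but are dropped from the
    transmurality counts; anything beyond a lumen gap — papillary muscles,
    trabeculae — is ignored). Rays that meet no tissue are invalid.
    """
    if n_rays < 36:
        raise ValidationError("n_rays must be >= 36")
    if step <= 0:
        raise ValidationError("step must be positive")
    labels = mask.labels
    h, w = labels.shape
    cr, cc = float(centre[0]), float(centre[1])

    corners = np.array([[0, 0], [0, w - 1], [h - 1, 0], [h - 1, w - 1]], float)
    rmax = float(np.max(np.hypot(corners[:, 0] - cr, corners[:, 1] - cc)))
    radii = np.arange(0.0, rmax + step, step)
    theta = 2.0 * np.pi * np.arange(n_rays) / n_rays
    drow = np.sin(theta)
    dcol = np.cos(theta)

    rows = np.rint(cr + radii[None, :] * drow[:, None]).astype(np.int64)
    cols = np.rint(cc + radii[None, :] * dcol[:, None]).astype(np.int64)
    inside = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
    lab = np.full(rows.shape, int(Label.BACKGROUND), np.uint8)
    lab[inside] = labels[rows[inside], cols[inside]]

    tissue = (lab == int(Label.VIABLE)) | (lab == int(Label.INFARCT))
    run_ok = tissue | (lab == int(Label.EXCLUDED))

    endo = np.full(n_rays, np.nan)
    epi = np.full(n_rays, np.nan)
    frac = np.full(n_rays, np.nan)
    infarcted = np.zeros(n_rays, bool)
    valid = np.zeros(n_rays, bool)

    for i in range(n_rays):
        hits = np.flatnonzero(tissue[i])
        if hits.size == 0:
            continue
        i0 = hits[0]
        after = ~run_ok[i, i0:]
        block_end = i0 + (int(np.argmax(after)) - 1 if after.any() else after.size - 1)
        in_block = hits[hits <= block_end]
        i1 = int(in_block[-1])
        n_tis = int(in_block.size)
        n_inf = int(np.count_nonzero(lab[i, in_block] == int(Label.INFARCT)))
        valid[i] = True
        endo[i] = radii[i0]
        epi[i] = radii[i1]
        frac[i] = n_inf / n_tis
        infarcted[i] = (n_inf - 0.5 * n_tis) * step > _TRANSMURAL_GUARD_PX

    if smooth_deg > 0:
        window = int(round(n_rays * smooth_deg / 360.0))
        if window % 2 == 0:
            window += 1
        endo = _circular_smooth(endo, valid, window)
        epi = _circular_smooth(epi, valid, window)

    mid_r = 0.5 * (endo + epi)
    points = np.stack([cr + mid_r * drow, cc + mid_r * dcol], axis=1)
    return MidlineTrace(
        theta=theta,
        endo_radius=endo,
        epi_radius=epi,
        midline_points=points,
        wall_thickness=epi - endo,
        infarct_fraction=frac,
        infarcted=infarcted,
        valid=valid,
        centre=(cr, cc),
        used_fallback_centre=used_fallback_centre,
    )


def midline_lengths(trace: MidlineTrace) -> tuple[float, float]:
    """Total and infarcted midline length of a trace, in pixels.

    Segments connect angularly adjacent valid rays (the polygon closes
    across the angular wrap when both end rays are valid). A segment counts
    fully towards the infarct length when both endpoints are infarcted rays
    and half when exactly one is — unbiased under refinement of the ray
    count.
    """
    n = trace.n_rays
    if trace.n_valid < 2:
        raise GeometryError("midline needs at least 2 valid rays")
    pts = trace.midline_points
    total = 0.0
    infarct = 0.0
    for i in range(n):
        j = (i + 1) % n
        if not (trace.valid[i] and trace.valid[j]):
            continue
        seg = float(np.hypot(*(pts[j] - pts[i])))
        total += seg
        marked = int(trace.infarcted[i]) + int(trace.infarcted[j])
        infarct += seg * (0.5 * marked)
    return total, infarct


def apply_ray_overrides(
    trace: MidlineTrace, overrides: Mapping[int, tuple[float, float]]
) -> MidlineTrace:
    """Manual midline adjustment: replace (endo, epi) radii on chosen rays.

    The scriptable stand-in for interactively dragging the traced midline:
    ``overrides`` maps a ray index to new ``(endo_radius, epi_radius)``.
    Midline points and thickness are recomputed; transmurality calls are
    kept.
    """
    endo = trace.endo_radius.copy()
    epi = trace.epi_radius.copy()
    valid = trace.valid.copy()
    for idx, (e0, e1) in overrides.items():
        if not (0 <= idx < trace.n_rays):
            raise ValidationError(f"override ray index {idx} out of range")
        if not (0 <= e0 < e1):
            raise ValidationError(f"override radii for ray {idx} need 0 <= endo < epi")
        endo[idx] = float(e0)
        epi[idx] = float(e1)
        valid[idx] = True
    mid_r = 0.5 * (endo + epi)
    drow = np.sin(trace.theta)
    dcol = np.cos(trace.theta)
    cr, cc = trace.centre
    points = np.stack([cr + mid_r * drow, cc + mid_r * dcol], axis=1)
    return MidlineTrace(
        theta=trace.theta.copy(),
        endo_radius=endo,
        epi_radius=epi,
        midline_points=points,
        wall_thickness=epi - endo,
        infarct_fraction=trace.infarct_fraction.copy(),
        infarcted=trace.infarcted.copy(),
        valid=valid,
        centre=trace.centre,
        used_fallback_centre=trace.used_fallback_centre,
    )


def trace_to_frame(trace: MidlineTrace) -> pd.DataFrame:
    """Per-ray audit table (theta, radii, midline point, transmurality)."""
    return pd.DataFrame(
        {
            "theta": trace.theta,
            "endo_radius": trace.endo_radius,
            "epi_radius": trace.epi_radius,
            "midline_row": trace.midline_points[:, 0],
            "midline_col": trace.midline_points[:, 1],
            "wall_thickness": trace.wall_thickness,
            "infarct_fraction": trace.infarct_fraction,
            "infarcted": trace.infarcted,
            "valid": trace.valid,
        }
    )
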