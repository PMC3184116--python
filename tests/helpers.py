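"""Shared test utilities: independent oracles and analytic fixtures."""

from __future__ import annotations

import numpy as np

from infarctsize.types import Label, LabelMask, MidlineTrace


def region_grow_reference(img, seeds, tolerance, forbidden=None, connectivity=8):
    """Pure-Python seeded region growing: the independent oracle.

    Same defined semantics as the production kernel — breadth-first from the
    seeds, neighbours in row-major order, running mean updated as pixels
    join, accepted pixels never re-tested — but implemented with plain
    Python queues and tuples, no numba and no vectorisation.
    """
    img = np.asarray(img, dtype=float)
    h, w = img.shape[:2]
    if connectivity == 8:
        offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        offsets = [(-1, 0), (0, -1), (0, 1), (1, 0)]
    forbidden_set = set()
    if forbidden is not None:
        rows, cols = np.nonzero(np.asarray(forbidden, bool))
        forbidden_set = set(zip(rows.tolist(), cols.tolist()))
    tol2 = float(tolerance) * float(tolerance)

    accepted = set()
    queue = []
    sr = sg = sb = cnt = 0.0
    for r, c in seeds:
        r, c = int(r), int(c)
        if (r, c) in accepted:
            continue
        accepted.add((r, c))
        sr += img[r, c, 0]
        sg += img[r, c, 1]
        sb += img[r, c, 2]
        cnt += 1.0
        queue.append((r, c))
    head = 0
    while head < len(queue):
        r, c = queue[head]
        head += 1
        for dr, dc in offsets:
            rr, cc = r + dr, c + dc
            if not (0 <= rr < h and 0 <= cc < w):
                continue
            if (rr, cc) in accepted or (rr, cc) in forbidden_set:
                continue
            mr, mg, mb = sr / cnt, sg / cnt, sb / cnt
            d0 = img[rr, cc, 0] - mr
            d1 = img[rr, cc, 1] - mg
            d2 = img[rr, cc, 2] - mb
            if d0 * d0 + d1 * d1 + d2 * d2 <= tol2:
                accepted.add((rr, cc))
                sr += img[rr, cc, 0]
                sg += img[rr, cc, 1]
                sb += img[rr, cc, 2]
                cnt += 1.0
                queue.append((rr, cc))
    mask = np.zeros((h, w), bool)
    for r, c in accepted:
        mask[r, c] = True
    return mask


def dice(a, b) -> float:
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom


def jaccard(a, b) -> float:
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return np.logical_and(a, b).sum() / union


def annulus_mask(
    size=128,
    centre=None,
    inner=20.0,
    outer=40.0,
    infarct=False,
    infarct_depth=None,
    infarct_sector=None,
):
    """Analytic annular LabelMask built directly from pixel-centre radii.

    ``infarct=True`` scars the whole wall; ``infarct_depth`` scars the outer
    fraction of the thickness; ``infarct_sector=(t0, t1)`` restricts scar to
    an angular sector.
    """
    if centre is None:
        centre = (size / 2.0, size / 2.0)
    rows, cols = np.mgrid[0:size, 0:size]
    dr = rows - centre[0]
    dc = cols - centre[1]
    radius = np.hypot(dr, dc)
    labels = np.full((size, size), int(Label.BACKGROUND), np.uint8)
    labels[radius < inner] = int(Label.LUMEN)
    wall = (radius >= inner) & (radius <= outer)
    labels[wall] = int(Label.VIABLE)
    scar = np.zeros((size, size), bool)
    if infarct:
        scar = wall.copy()
    elif infarct_depth is not None:
        scar = wall & (radius >= outer - infarct_depth * (outer - inner))
    if infarct_sector is not None:
        ang = np.mod(np.arctan2(dr, dc), 2 * np.pi)
        t0, t1 = infarct_sector
        scar &= np.mod(ang - t0, 2 * np.pi) < (t1 - t0)
    labels[scar] = int(Label.INFARCT)
    return LabelMask(labels=labels)


def circular_trace(radius=30.0, n_rays=360, centre=(64.0, 64.0), infarcted=None):
    """Exact circular MidlineTrace (analytic, no rasterisation)."""
    theta = 2 * np.pi * np.arange(n_rays) / n_rays
    r = np.full(n_rays, float(radius))
    pts = np.stack(
        [centre[0] + r * np.sin(theta), centre[1] + r * np.cos(theta)], axis=1
    )
    if infarcted is None:
        infarcted = np.zeros(n_rays, bool)
    infarcted = np.asarray(infarcted, bool)
    return MidlineTrace(
        theta=theta,
        endo_radius=r - 5,
        epi_radius=r + 5,
        midline_points=pts,
        wall_thickness=np.full(n_rays, 10.0),
        infarct_fraction=infarcted.astype(float),
        infarcted=infarcted,
        valid=np.ones(n_rays, bool),
        centre=centre,
    )
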