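# Methods

This note documents the models, numerical choices and limitations behind
`infarctsize`. It is the package's own account of its science; every number
quoted here is recomputed by the test suite or by `scripts/acceptance.py`.

## Pixel classification

A section image is partitioned into five classes — background, lumen,
viable myocardium, infarct (scar), excluded — in a fixed precedence order:
exclusion polygons first, then background, then lumen, then viable, with
scar as the residual tissue.

**Background.** The unstained slide is bright in all channels. A pixel is
"pale" when `min(R, G, B) >= 220` (default `whiteness`); background is the
set of pale pixels reachable from the image border by 4-connected flood
fill. The connectivity is deliberately tighter than for tissue growth: a
diagonal leak through a one-pixel tissue gap is far more damaging for the
background fill (it would drain the lumen) than for tissue. Consequence:
pale pixels *enclosed* by tissue are not background — an enclosed pale
lumen is reachable only through the user's lumen seed, and enclosed
intramural blood that no region claims ends up in the residual scar class.
That behaviour is documented rather than hidden; such regions should be
removed with an exclusion polygon when they matter.

**Seeded region growing.** Lumen and viable myocardium are grown from user
seeds. The homogeneity criterion is the Euclidean RGB distance between the
candidate pixel and the *running mean* colour of the region so far;
running-mean aggregation tolerates gradual staining gradients that a
fixed-seed-colour criterion would cut off. The expansion order is part of
the algorithm's definition, not an implementation detail: breadth-first
from the seeds (in their given order), neighbours tested in row-major
order, 8-connectivity, the mean updated as each pixel joins, an accepted
pixel never re-tested. A pixel rejected at one moment may be re-tested
later from another accepted neighbour. This makes results reproducible bit
for bit, and the production kernel (numba) is checked for exact equality
against an independently written pure-Python implementation of the same
definition on random images.

The default tolerance is 60 (RGB distance units, image range 0–255). On
trichrome-like colours the class separations are large (viable–scar ≈ 167,
tissue–pale ≥ 260), so any tolerance in roughly 30–120 gives the same
segmentation; 60 sits in the middle of that plateau. It is adjustable
globally (`--tolerance`) and per section (`tolerance` in the seed file),
mirroring the adjustable merging criterion of interactive tools.

**Pre-filtering.** A 3×3 median filter per channel (disableable) suppresses
sensor/JPEG speckle. A median keeps the majority side's colour at a hard
class boundary, so unlike a linear blur it does not manufacture blend
pixels that would fall into the residual scar class.

Lumen and viable growth may not enter background, excluded regions, or each
other (lumen wins, being grown first). Forbidding background to the tissue
grows follows from the assignment order — without it a pale lumen seed
would flood the pale slide.

## Midline geometry

Rays are cast from the lumen centroid (wall centroid, flagged, when the
lumen is obliterated near the apex) at `n_rays = 360` equally spaced
angles, sampling the label map every 0.5 px with nearest-neighbour lookup.
Per ray, only the *first* contiguous tissue run defines the wall: papillary
muscles or trabeculae beyond a lumen gap are ignored. Excluded samples
inside the run neither break it nor count towards transmurality.

**Transmurality rule.** A ray is infarcted when scar occupies more than
half of the wall's radial thickness. The raw per-ray fraction is
`n_infarct / n_tissue` over the run's samples. The *call*, however,
requires the majority to exceed the measurement resolution: the three run
boundaries (endocardial, viable/scar transition, epicardial) are each
localised only to about half a pixel by nearest-neighbour sampling on a
rasterised mask, and the bias is systematic at lattice-aligned angles.
Measured on half-thickness phantoms across image sizes 256–1024 and wall
thicknesses 15–60 px, the worst-case spurious majority is 1.0 px of wall
thickness; the call therefore requires the scar extent to exceed half the
thickness by more than a 1.5 px guard. A fraction of exactly 0.5 never
marks a ray infarcted; the price is insensitivity to true transmurality in
the narrow band (50%, 50% + 1.5 px/thickness], i.e. 55% on a 30 px wall.

**Radial smoothing.** Raw per-ray endo/epi radii zig-zag at the ±0.5 px
pixel scale. Summing raw chords would inflate the midline length by several
percent and make it depend on the ray count (the zig-zag amplitude stays
fixed while the angular chord shrinks). The radii are therefore denoised
with a circular moving average over a fixed 3° angular window
(`smooth_deg`, 0 disables) before midline points are formed. The window is
fixed in angle, not in rays, so refining `n_rays` changes the total length
by well under 0.5%. Transmurality counts use the raw samples, not the
smoothed radii.

**Lengths.** The midline length is the perimeter of the polygon through the
midline points of angularly adjacent valid rays (closing across the wrap).
A segment counts fully towards the infarcted length when both endpoints are
infarcted rays and half when exactly one is — the half-credit rule is
unbiased under ray-count refinement. Sections with fewer than two valid
rays have no midline score; they are flagged and dropped from the per-heart
mean rather than scored zero (an undefined measurement is not a 0%
infarct). The same applies to the area score when no wall pixels exist.

## Scores and aggregation

Area method: `100·|scar| / (|scar| + |viable|)`. The denominator is the LV
wall only — lumen, background and excluded pixels enter neither term,
consistent with manual planimetry of the myocardium. Midline method:
`100·L_infarct/L_total`. Per heart, both methods are averaged *unweighted*
over the scored sections; 0% sections count.

## Phantom generator

The generator emulates what the pipeline needs from a trichrome section,
nothing more: an annular wall (default endo 150 px, epi 180 px in a
512×512 frame — a dilated, remodelled LV with a 30 px wall) around a pale
lumen on a pale slide; a scar sector `(theta0, theta1)`; optional wall
thinning inside the sector (factor in (0,1], chronic scars thin the wall);
optional partial transmural depth (scar limited to the outer fraction of
the wall); hard class edges plus i.i.d. Gaussian noise (default σ = 4,
seeded, clipped, bit-reproducible); default colours viable (170, 60, 70),
scar (70, 90, 200), pale (245, 245, 245). Every colour pair except
lumen/background must be ≥ 5σ apart so the truth is recoverable;
lumen and background may share a colour because the pipeline separates them
spatially (enclosure), not chromatically. An optional decoy blob of
viable-coloured tissue outside the wall stands in for the right ventricle;
its truth label is "excluded" since it is not LV.

Ground truth: the noiseless class map; `true_area_pct` from its pixel
counts (hence exactly consistent with `area_score` on the truth mask);
`true_midline_pct = 100·sector/2π` for transmural scars (depth > 0.5) and 0
otherwise.

The wall geometry matters for one subtle reason: the midline of a thinned
sector sits at a smaller radius than the healthy midline, so its arc is
shorter and the measured midline percentage undershoots the angular
fraction. With the default 30 px wall this bias peaks around 1.6 points at
thinning 0.5 (half-circle scar); thicker walls relative to the radius make
it worse. The closed-form truth keeps the angular fraction; the bias is
part of the measured error budget.

What the phantoms do **not** emulate: staining variability and gradients,
texture, fibre structure, tissue folds and tears, scanner/illumination
effects, non-annular anatomy. Passing the phantom suite therefore
demonstrates the geometric and algorithmic correctness of the pipeline, not
robustness to real histological variability — on real sections the seeds,
tolerance and exclusion polygons are the operator's controls for exactly
that variability.

## Agreement statistics

Bland–Altman on pre-averaged pairs: differences `d = b − a`, bias =
mean(d), `sd` with the n−1 denominator, limits of agreement `bias ±
1.96·sd` (the classic 1.96 multiplier, not a t quantile), CIs from the t
distribution with n−1 df using standard errors `sd/√n` (bias) and
`√(3·sd²/n)` (each limit); CIs need n ≥ 3 and collapse to points at zero
variance. Pearson r by the product-moment formula; zero variance is an
error, not NaN. Published acceptance bounds for this kind of comparison
(bias within ±2 points, concordance limits within ±7 per heart) are context
for interpreting reports, not enforced thresholds.

## Problem sizes

The test suite and acceptance script run phantoms at 512×512 (the
20-phantom recovery grid, ~4 s total after JIT warm-up), 256×256 (the
5-heart × 12-section validation study and the batch CLI check) and smaller
analytic masks for geometry unit tests; the oracle-equivalence checks use
100 random images up to 32×32. These sizes put every boundary several
pixels wide while keeping the whole self-validation in seconds.

## Known limitations

- Colour-based classification assumes trichrome-like class separation; no
  stain normalisation or colour deconvolution is attempted.
- The transmurality call has the resolution-guard dead band described
  above; very thin walls (≲ 4 px) cannot be called transmural at all.
- Pale material enclosed by tissue that no seed claims ends up as scar
  unless excluded.
- The midline of strongly non-convex walls is defined by the first wall run
  per ray; unusual anatomy may need per-ray overrides
  (`apply_ray_overrides`).
- Per-heart means are unweighted; no volume weighting or 3-D
  reconstruction across sections.
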