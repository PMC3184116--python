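# infarctsize

Semi-automated quantification of myocardial infarct size from
Masson's-trichrome-stained left-ventricle (LV) cross-sections.

In rodent models of surgically induced myocardial infarction (permanent
coronary-artery ligation), infarct size is the key outcome measure and is
traditionally obtained by manual histological planimetry — slow and highly
operator-dependent. `infarctsize` replaces the manual tracing with a
scriptable, reproducible pipeline: the user supplies, per section, a few
seed pixels for the LV lumen and the viable (muscle-red) myocardium, and the
package does the rest. The heterogeneous collagen-blue scar is deliberately
*not* seeded: it is recovered as the residual tissue class.

## Method

Per section (RGB photograph of a transverse LV slice):

1. **Segmentation** — the pale slide background is removed by border flood
   fill; lumen and viable myocardium are grown from the seeds by *seeded
   region growing* (a candidate pixel joins when the Euclidean RGB distance
   to the running mean colour of the region is ≤ a tolerance, default 60);
   scar = remaining tissue. Artifacts (right ventricle, blood in the lumen)
   are removed with exclusion polygons.
2. **Midline tracing** — rays are cast from the lumen centroid at 360
   equally spaced angles; per ray the first contiguous wall run gives the
   endocardial and epicardial radii and the midline point halfway between
   them. A ray is *infarcted* when scar occupies more than 50% of the wall's
   radial thickness there.
3. **Scores** — two standard planimetry measures, per section:

   - area method: `100 · |scar| / (|scar| + |viable|)` (pixel areas; the LV
     wall only — lumen and background excluded),
   - midline-length method: `100 · L_infarct / L_total` along the traced
     midline polygon.

   The per-heart infarct size is the unweighted mean over the heart's
   (≈12, apex-to-base) representative sections.

Chronic infarcts thin the wall, which compresses the area score relative to
the midline-length score — the package reproduces that ordering on thinned
phantoms.

The package also ships a **phantom generator** (annular wall, sector scar,
optional thinning and partial transmural depth, closed-form ground truth)
and **agreement statistics** (Bland–Altman bias and limits of agreement
with t-based confidence intervals; Pearson r) for validating scores against
manual or ground-truth values.

## Worked example

Render a phantom section with a 120° transmural scar sector and the wall
thinned to 70% inside it, then quantify it:

```bash
infarctsize phantom --out-dir demo --size 512 --sector-deg 120 --thinning 0.7 --seed 9
infarctsize quantify --images 'demo/heart_s??.png' --seeds demo/seeds.yaml \
    --out demo/results.csv
```

which prints

```
heart: 1 section(s), mean area 25.47%, mean midline 33.05%
wrote demo/results.csv
```

The truth file written next to the phantom states `true_area_pct = 25.46`
and `true_midline_pct = 33.33`: the area score recovers the truth to 0.01
points, and the midline score to 0.28 points — and the area score sits
below the midline score because the thinned scar sector contributes less
wall *area* than midline *arc*. `results.csv` holds one row per section
plus a `MEAN` row per heart:

```
heart_id,section_id,area_pct,midline_pct
heart,heart_s01,25.472878749955303,33.05408934341748
heart,MEAN,25.472878749955303,33.05408934341748
```

The same pipeline is available as a library (`quantify_section`,
`quantify_heart`, `segment_section`, `cast_rays`, `bland_altman`, ...); the
seed file format is documented in `infarctsize.io`.

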