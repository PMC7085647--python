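# Methods

## Problem and model

Flowering intensity — how much of a breeding plot is in bloom — is scored
visually in the field, which is slow and rater-dependent. `floralquant`
estimates it from color imagery under a deliberately simple, transparent
model: flowers, canopy, soil and common noise objects occupy distinct
regions of color space, so per-pixel inequalities on channels (and channel
differences), followed by per-component shape and context filters, recover
the flower pixels. No training data is required; the alternative k-means
path needs no thresholds at all for segmentation, only a color rule to name
the flower clusters.

Two features summarize an image or plot:

- flower area `|F|` in pixels;
- flowers% `= 100·|F| / |C ∪ F|`, where `C` is the canopy mask. The union
  denominator reflects that petals rarely satisfy the green canopy rule;
  it also guarantees flowers% ≤ 100 by construction.

Features are related to visual ratings and yield by Pearson product-moment
correlation with a two-sided t-test; p-values are reported unadjusted with
conventional significance stars (no multiplicity correction is applied,
matching common practice for these screening tables). Rating scales (0–10
or 0–100%) pass through untransformed since r is scale- and
shift-invariant.

## Radiometric correction

Each band is multiplied by `g_b = ρ_b / mean(panel_b)` where ρ is the
nominal reflectance of a diffuse panel in the frame. The panel region is
user-supplied (no automatic panel detection); nominal reflectance defaults
to 0.99 per band — the convention for white Spectralon-type standards —
and is overridable. Output is on a reflectance scale; values above 1 occur
when scene specularities outshine the panel and are clipped at 1.5 and
logged rather than discarded. Correction is supported per image; batch
policy (one panel per session) is left to the caller. A global
illumination gain applied to a scene cancels exactly under this correction,
which the tests verify pixelwise.

## Color spaces and threshold rules

Conversion to CIE L\*a\*b\* uses sRGB companding with the D65 white point —
the ubiquitous convention for consumer-camera imagery; rasters containing a
NIR band are rejected for this conversion. Canopy defaults to `a* < −13`:
green vegetation sits far on the negative a\* axis (the default canopy
paint color has a\* ≈ −43.6, soil ≈ +11.3), so the printed pea constant
separates them with a wide margin.

Threshold rules are declarative — an OR of AND-blocks of atomic
inequalities like `R > 200` or `G - R <= 20` — and are stored in YAML
crop–sensor profiles. Constants are scale-specific: profiles hold separate
raw_8bit and reflectance variants and no implicit rescaling is ever
performed (a rule/scale mismatch raises). Rules are evaluated strictly per
pixel with no spatial smoothing. Only the pea constants (canopy `a* < −13`;
flower `R,G,B > 200, G−R ≤ 20`) and the canola/pea k-means centroid rules
are published values; the canola/camelina/chickpea threshold profiles are
editable package defaults patterned on the canola centroid rule (yellow =
high R and G, low B) and are marked as such in the YAML files.

## Noise removal

Candidates are labeled with 8-connectivity by default (diagonally touching
petals merge; configurable). Per component:

- **Morphology** — keep iff `min_area ≤ area ≤ max_area`,
  `axis_ratio ≤ max_axis_ratio`, `solidity ≥ min_solidity`. Axis ratio is
  major/minor length of the ellipse with identical second central moments
  (4·√eigenvalue convention); a single pixel is defined to have ratio 1 and
  solidity 1, and a perfectly collinear component has ratio ∞ (maximally
  elongated, always removed by any finite limit). Numeric limits are not
  published; the package defaults are `min_area = 5 px`,
  `max_area = 2%` of the image, `max_axis_ratio = 4`, `min_solidity = 0.6`,
  all profile-overridable. Area limits are resolution-dependent;
  `MorphologyLimits.scaled(f)` divides `min_area` by f² for imagery
  downsampled by f.
- **Canopy adjacency** — keep iff the component overlaps canopy or its
  exterior ring (8-connected dilation minus the component, width 1 by
  default) intersects canopy. "Peripheral pixels" are interpreted as this
  exterior ring. At coarse resolution a one-block rim of mixed
  flower/canopy color separates petals from pure canopy, so degraded or
  aerial imagery should use ring width 2; the width is an explicit
  parameter.

Both filters are independent per-component predicates, so their order is
irrelevant; the tests assert this on random masks, and the adjacency filter
is checked for exact agreement against a brute-force enumeration of every
pixel's 8-neighborhood.

## k-means path

Lloyd's algorithm with squared Euclidean distance and k-means++ (D²)
seeding, k = 6, 3 replicates with seeds `seed, seed+1, seed+2`, iteration
cap 100, and the singleton action: an emptied cluster is re-seeded with the
point farthest from its centroid. The implementation is in-package because
the pipeline asserts per-iteration inertia monotonicity and deterministic
replicate seeding, which generic library calls do not expose; an external
k-means implementation instead serves as an independent quality oracle in
the tests (best-of-3 inertia within 5% of a 50-restart reference).
Clustering runs on the image min–max rescaled to [0, 1] globally (a
constant image maps to 0 to avoid division by zero). The flower rule is
applied to centroids, not pixels; by default all pixels are clustered
(not only canopy), which reproduces the method's known white-flower failure
mode — pale soil glints join the flower cluster — and a canopy-mask option
is available. Flower area is the only feature extracted on this path, so
flowers% tables always come from the threshold path.

## Plot grid

The corner quadrilateral (TL, TR, BR, BL in pixel x/y) is divided by
bilinear interpolation; cell (i, j) spans
`[j/n_cols, (j+1)/n_cols] × [i/n_rows, (i+1)/n_rows]` in the unit square,
optionally shrunk by `alley_frac` per side. ROIs trim `margin_frac`
(default 0.1 — "central part of the plot"; no published number) of each
cell per edge. The construction is exactly affine-equivariant, and cells
tile the quadrilateral up to rasterization (±0.5% in tests). Field
rotation/cropping is handled by the corner geometry rather than resampling
the raster — equivalent and lossless. Serpentine plot ordering is a flag
since field books vary. Corner order is validated (self-intersecting or
collinear corners raise).

## GSD arithmetic

`GSD [mm] = altitude [m] · 1000 · pixel pitch [µm] · 10⁻³ / focal length
[mm]`, linear in altitude for a fixed sensor, so
`gsd(h₂) = gsd(h₁)·h₂/h₁`. Resolution adequacy uses the rule of thumb that
a flower must span at least `factor` pixels (default 2, the conservative
end of the 2–3× guidance): ratio = flower size / GSD.

## Synthetic scenes

The generator emulates the imaging situation, not its photometric realism:
flat-colored soil (120,85,60), canopy ellipse blobs (40,130,50) grown to a
target coverage (default 0.5), elliptical flowers (white 230,230,230 or
canola-yellow 230,210,40; default 30 per 200×200 scene, radii 3–5 px ≈
proximal-GSD-scale pea flowers), 1-px straw polylines (220,215,205, length
15–35), soil-glint disks (235,230,224), an optional 252-valued panel patch,
and a global illumination gain. Colors are chosen so every class is
classified unambiguously by the printed pea rules (margins of tens of
units), which is what makes pixel-exact recovery a meaningful contract.
Flowers are placed wholly inside canopy with a pure-canopy ring (erosion by
max radius + 4) and ≥3 px apart; noise is placed ≥3 px off canopy so that
adjacency, not color, removes it. All randomness flows from one seeded
generator; identical parameters give bit-identical scenes.

What the generator does **not** emulate — shadow and uneven illumination,
specular petals, wind blur, overlapping flower clumps, senescent-leaf
color gradients, stitching artifacts — is exactly the territory where the
field method degrades; passing these tests demonstrates correctness of the
mechanics, not field accuracy. `degrade_resolution` (block-mean
downsampling, GSD multiplied by the factor) emulates higher-altitude
acquisition including spectral mixing: a flower smaller than a block stops
passing its color rule, which reproduces the small-flower recall collapse
that motivates the 2–3× GSD rule.

## Numerical and design choices

- Masks are boolean numpy arrays; components use scikit-image labeling and
  region properties, cross-checked against in-package moment code.
- `rescale_to_unit` is global min–max, not per band (per-band would distort
  hue relations the centroid rules depend on).
- Pearson r uses the standard product-moment estimator; zero variance
  raises an error rather than returning NaN.
- The degenerate-k guard triggers when k exceeds the number of pixels;
  duplicate colors are legal (a 3-color scene under k = 6 resolves via the
  singleton action with zero inertia).
- Replicate and scene seeds are small integer offsets from the master seed;
  nothing uses global RNG state.
- Default problem sizes (200×200 proximal scenes, 480×360 orthomosaics,
  20-scene batches) keep the full suite and the acceptance script in the
  tens of seconds while leaving every object tens of pixels across —
  comfortably above all morphology limits.

## Known limitations

- Threshold constants for crops other than pea are unpublished placeholders
  and must be tuned per sensor and field before real use.
- No shadow/illumination compensation; deeply shadowed flowers fail the
  color rules (and the generator does not model them).
- No orthomosaic stitching, flight planning, vignetting or lens-distortion
  handling; orthomosaics are expected pre-stitched.
- The adjacency rule assumes noise is spatially separated from canopy;
  straw lying *on* the canopy would survive it (the axis-ratio limit is
  then the only defense).
- Supervised detectors (SVM/CNN) are out of scope by design.
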