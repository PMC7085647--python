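# floralquant

Image-based phenotyping of flowering intensity in cool-season crop breeding
trials (canola, camelina, pea, chickpea).  Visual scoring of flowering is
slow and subjective; `floralquant` quantifies it from proximal plot
photographs (tripod/pole, ~1.6–2.2 m above ground) and UAV orthomosaics
(15–30 m), producing per-image or per-plot **flower area** (pixels) and
**flowers%** and relating them to visual ratings and seed yield.

## What it computes

**Threshold pipeline** (fully automated, per image):

1. *Radiometric correction* — a reference panel of known reflectance ρ in
   the frame fixes a per-band gain g_b = ρ_b / mean(panel_b), cancelling
   illumination differences between images.
2. *Canopy segmentation* — the image is converted from sRGB to CIE L\*a\*b\*
   (D65) and canopy is taken where **a\* < −13** (green has strongly
   negative a\*).
3. *Flower candidates* — declarative channel-threshold rules per crop and
   sensor; for white pea flowers in 8-bit RGB: **R, G, B > 200 and
   G − R ≤ 20**.
4. *Noise removal* — connected components that are too small/large, too
   elongated (major/minor moment-ellipse axis ratio, e.g. wheat straw), or
   insufficiently solid (area / convex hull) are dropped; remaining
   components are kept only if their peripheral pixel ring touches the
   canopy mask — bright soil glints and artificial objects lie off-canopy
   and fail this *canopy adjacency* test.
5. *Features* — flower area in pixels and
   flowers% = 100 · |flower| / |canopy ∪ flower|.

**k-means pipeline** (unsupervised alternative): pixels of the unit-rescaled
image are clustered by Lloyd's algorithm (k = 6, squared Euclidean,
k-means++ seeding, 3 replicates, iteration cap 100, farthest-point
re-seeding of emptied clusters) and clusters whose *centroid* satisfies a
color rule — e.g. canola yellow: (R > 0.75, G > 0.75, B < 0.25) or
(R > 0.45, G > 0.55, B < 0.12) — form the flower mask.  Flower area is the
only feature on this path.

**Aerial mode**: the four corners of the field are supplied by the user;
bilinear interpolation divides the corner quadrilateral into the
rows × cols plot grid, each plot is trimmed by a margin fraction per edge,
and features are computed inside each plot ROI.

**Statistics & resolution**: Pearson product-moment correlation of features
against visual ratings / yield, and ground-sample-distance arithmetic —
GSD [mm] = altitude · pixel pitch / focal length, scaling linearly with
altitude; imagery is adequate for a flower only when the flower is ≥ 2–3 ×
the GSD, otherwise petals mix spectrally inside single pixels.

A seeded synthetic-scene generator (green canopy on brown soil, white or
yellow flower ellipses, straw lines, soil glints, reference panel) provides
exact pixel-level ground truth for every stage.

## Worked example

```python
import floralquant as fq

params = fq.SceneParams(flower_count=25, straw_count=8, glint_count=4, seed=7)
img, truth = fq.generate_plot_image(params)

profile = fq.CropSensorProfile.builtin("pea")
canopy = fq.segment_canopy(img, profile)
candidates = fq.segment_flower_candidates(img, profile)
flowers, report = fq.denoise_report(candidates, canopy, profile.morphology)

print("true flower area (px):", truth.flower_area_px)
print("candidate area (px):  ", int(candidates.sum()))
print("denoised area (px):   ", int(flowers.sum()))
print("flowers%:             ", round(fq.flowers_percentage(flowers, canopy), 2))
print(report[~report.kept].drop_reason.value_counts().to_string())
```

```
true flower area (px): 1263
candidate area (px):   1494
denoised area (px):    1263
flowers%:              6.23
drop_reason
axis_ratio            8
no_canopy_neighbor    4
```

The color rule alone over-detects (1494 px: straw and glints share the
white-flower reflectance); the 8 elongated straw lines fall to the
axis-ratio limit and the 4 off-canopy glints to the adjacency rule, leaving
exactly the painted flower pixels.

The same flows are available from the shell:

```sh
floralquant simulate --mode aerial --rows 3 --cols 4 -o sim/
floralquant aerial sim/orthomosaic.png \
    --corners 20 20 460 20 460 350 20 350 --rows 3 --cols 4 -o out/
floralquant correlate out/plot_features.csv sim/ratings.csv
floralquant gsd --gsd 4 --altitude 15 --scale-to 30 --flower-size 20
# GSD: 4.00 mm/pixel
# GSD at 30 m: 8.00 mm/pixel
# flower/GSD ratio: 2.50 -> adequate (factor 2)
```

## Layout

- `floralquant.raster` — image I/O, panel-based radiometric correction, sRGB → CIE L\*a\*b\*
- `floralquant.rules` — threshold rules, crop–sensor profiles (YAML), canopy/flower segmentation
- `floralquant.noise` — connected-component morphology and canopy-adjacency filters
- `floralquant.cluster` — Lloyd/k-means++ pixel clustering with centroid color rules
- `floralquant.grid` — corner-quadrilateral plot-grid interpolation and ROI features
- `floralquant.stats` — flowers%, Pearson correlation, GSD and resolution adequacy
- `floralquant.synthetic` — seeded scene/orthomosaic generator with exact ground truth
- `floralquant.pipeline`, `floralquant.cli` — end-to-end runs and the `floralquant` command

Only the pea rules above are published constants; canola/camelina/chickpea
threshold profiles ship as clearly marked editable defaults (see
`src/floralquant/profiles/` and `docs/methods.md`).
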