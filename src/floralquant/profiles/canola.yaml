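# Canola profile.  The k-means centroid rule is the published one
# ((R,G > 0.75, B < 0.25) OR (R > 0.45, G > 0.55, B < 0.12)); the canopy and
# flower threshold rules are NOT published for this crop and ship as editable
# defaults patterned on that color rule (yellow = high R and G, low B; canopy
# via the green a* criterion).
crop: canola
sensor: C-RGB
canopy_rule: ["a* < -13"]
flower_rule:
  raw_8bit:
    - ["R > 191", "G > 191", "B < 64"]
  reflectance:
    - ["R > 0.75", "G > 0.75", "B < 0.25"]
morphology:
  min_area_px: 5
  max_axis_ratio: 4.0
  min_solidity: 0.6
  max_area_frac: 0.02
kmeans_color_rule:
  - ["R > 0.75", "G > 0.75", "B < 0.25"]
  - ["R > 0.45", "G > 0.55", "B < 0.12"]
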