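# Pea / C-RGB profile.
# canopy_rule (a* < -13) and the raw_8bit flower rule (R,G,B > 200, G-R <= 20)
# are the published constants for this crop-sensor pair; the reflectance-scale
# flower constants are the same rule re-expressed for panel-corrected imagery
# (8-bit constant x 0.99/252 for a near-white panel) and are editable defaults.
crop: pea
sensor: C-RGB
canopy_rule: ["a* < -13"]
flower_rule:
  raw_8bit:
    - ["R > 200", "G > 200", "B > 200", "G - R <= 20"]
  reflectance:
    - ["R > 0.784", "G > 0.784", "B > 0.784", "G - R <= 0.078"]
morphology:
  min_area_px: 5
  max_axis_ratio: 4.0
  min_solidity: 0.6
  max_area_frac: 0.02
# centroid color rule for the k-means path, unit scale
kmeans_color_rule:
  - ["R > 0.75", "G > 0.75", "B > 0.75"]
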