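# Chickpea profile — white flowers like pea.  The published pea flower rule
# is stated to hold for all pea images; for chickpea these constants are
# editable defaults reusing the white-flower archetype.
crop: chickpea
sensor: C-RGB
canopy_rule: ["a* < -13"]
flower_rule:
  raw_8bit:
    - ["R > 200", "G > 200", "B > 200", "G - R <= 20"]
  reflectance:
    - ["R > 0.784", "G > 0.784", "B > 0.784", "G - R <= 0.078"]
morphology:
  min_area_px: 4
  max_axis_ratio: 4.0
  min_solidity: 0.6
  max_area_frac: 0.015
kmeans_color_rule:
  - ["R > 0.75", "G > 0.75", "B > 0.75"]
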