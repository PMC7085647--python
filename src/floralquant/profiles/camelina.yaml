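# Camelina profile — small yellow flowers.  No thresholds are published for
# this crop; all rules are editable defaults copied from the canola yellow
# archetype.  Morphology area limits are tighter because camelina flowers are
# 3.5-4.5 mm across.
crop: camelina
sensor: MS1
canopy_rule: ["a* < -13"]
flower_rule:
  raw_8bit:
    - ["R > 191", "G > 191", "B < 64"]
  reflectance:
    - ["R > 0.75", "G > 0.75", "B < 0.25"]
morphology:
  min_area_px: 3
  max_axis_ratio: 4.0
  min_solidity: 0.6
  max_area_frac: 0.01
kmeans_color_rule:
  - ["R > 0.75", "G > 0.75", "B < 0.25"]
  - ["R > 0.45", "G > 0.55", "B < 0.12"]
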