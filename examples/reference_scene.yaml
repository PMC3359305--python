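background_beta: 1.0
height: 512
illumination:
- 0.1
- 512
mantle_beta: 2.5
mantle_box:
- - 30
  - 30
- 150
mantle_from_object: 1
mantle_margin: 30
noise_sigma: 0.005
objects:
- beta: 2.5
  center:
  - 330
  - 160
  gain: 1.0
  radii:
  - 145
  - 145
  shape: ellipse
- beta: 1.0
  center:
  - 140
  - 380
  gain: 1.0
  radii:
  - 110
  - 115
  shape: ellipse
seed: 0
width: 512
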