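# Example session configuration.
#
# Angles are degrees per side and must sum to 180; coordinates are image
# pixels (origin top-left, y down).  The qc block may be omitted: the
# likelihood cut-off defaults to 0.95 and the distance threshold to k = 3.
fps: 25
field_angles:
  frontal_halfwidth: 15    # chick frontal field, from the midline
  lateral_width: 135       # chick lateral (monocular) field
  blind_halfwidth: 30      # behind the head, per side
stimuli:
  - {id: cylinder, type: circle, center: [640, 70], radius: 29}
  # - {id: dot, type: point, center: [100, 200]}
  # - {id: bar, type: segment, border_a: [300, 50], border_b: [400, 50]}
zones:
  - {id: near, rect: [0, 0, 1280, 360]}
  - {id: far, rect: [0, 360, 1280, 720]}
qc:
  likelihood_cutoff: 0.95
  distance_threshold_k: 3
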