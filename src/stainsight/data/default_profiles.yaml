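# Default stainsight pipeline configuration.
#
# stain_deficits are the bundled per-band intensity deficits (R, G, B) of each
# object class relative to a 225-mean bright-field background, measured at high
# magnification: beads are dark in all bands; unstained cells sit just above the
# detection floor (>=15 in every band); each dye keeps its own hue brightest
# (smallest deficit: safranin red, trypan/methylene blue and crystal violet blue).
optics_preset: microscope_4x
stain_deficits:
  bead: [125, 120, 140]
  unstained: [15, 15, 30]
  TB: [50, 40, 40]
  safranin: [25, 135, 100]
  MB: [100, 100, 45]
  CV: [100, 115, 30]
# Stage-1 gate: anything less than this deficit in some band is background.
stage1_min_deficit: 10
# Per-pixel foreground criterion for segmentation (all bands must exceed it).
min_deficit: 10
# null -> area of a 2 um disk at the preset's pixel scale.
min_object_area: null
# Regions larger than this multiple of the median area count as clusters.
cluster_cutoff_factor: 1.6
# Upper bound of the ultra-low (near detection floor) density class.
ultra_low_max: 1000
# r^2 needed for a "linear" verdict over the counting range.
r2_threshold: 0.95
seed: 0
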