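# Methods

## The measurement model

A bright-field image of the chip's visualization compartment is modelled as
a bright, near-uniform background with dark absorbing objects on it. The
background is per-band Gaussian: mean 225 in each 8-bit band (the value the
assay is calibrated around), default noise sd 3, clipped to [0, 255]. Each
object — bead, unstained cell, or stained cell — is a filled disk with a
per-band *deficit* `d_c` below the background. The bundled class profiles
are:

| class      | d_R | d_G | d_B | dominant band |
|------------|-----|-----|-----|---------------|
| bead       | 125 | 120 | 140 | —             |
| unstained  | 15  | 15  | 30  | —             |
| TB         | 50  | 40  | 40  | B             |
| safranin   | 25  | 135 | 100 | R             |
| MB         | 100 | 100 | 45  | B             |
| CV         | 100 | 115 | 30  | B             |

The dominant band — the dye's own hue — keeps the smallest deficit (the
stained cell stays brightest in that band). Trypan blue's green and blue
deficits tie at 40; the profile declares blue dominant on chemical grounds,
while the data-driven `dominant_band()` reports the tie explicitly.

### Rendering as transmittance stacking

Disks are composited multiplicatively: each object carries a per-band
transmittance `T_c = (225 − d_c)/225`, and a pixel covered by several
objects is attenuated by the product of their transmittances, the standard
absorbance picture for stacked, weakly scattering layers in bright field.
Two consequences drive the package's behaviour:

- a single non-overlapping disk renders at exactly `225 − d_c`, so noiseless
  scenes are an exact oracle for segmentation and color analysis;
- magnet-gathered conjugate piles (clustered placement with overlapping
  disks) darken with stacking depth, which is why a phone photo of a
  stained pile differs from an undyed one by far more than the single-cell
  deficit alone would suggest.

No point-spread function, chromatic aberration or illumination gradient is
modelled; `blur_sigma` offers optional Gaussian edge softening (default 0,
so areas stay analytic).

### Geometry and optics

Pixel scales assume a 6.5 µm camera pixel: 1.625 / 0.65 / 0.325 / 0.13 µm/px
at the 4×–50× objectives. The quantitative (area-ratio) analysis runs at 4×,
the package default. The phone preset uses 8 µm/px, blur sigma 1 px and
noise sd 4 — a 12 MP camera ~10 cm from the chip. Physical sizes: beads
4.5 µm; K562 cells default to 15 µm (a typical lymphoblast diameter — the
assay itself only fixes the 2.5× ratio to lymphocytes, so this is a
declared, configurable default); patient lymphocytes 15/2.5 = 6 µm. Beads
are omitted from the lymphocyte preset scenario since nano-bead conjugates
are unresolvable at these scales.

Placement is rejection sampling for `non_overlapping` fields (bounded
retries, then a typed error naming the density) and Gaussian clumps around
cluster centres for `clustered` piles. One `numpy` Generator seeded per
scene drives every draw, so identical `(SceneSpec, seed)` gives bit-identical
images and ground truth.

## Segmentation

The background estimate takes pixels above an Otsu threshold on luminance
and reports their per-band mean and sd. If the Otsu split separates the two
candidate populations by less than 10 intensity units the frame is treated
as object-free and the full frame is averaged — otherwise a pure-noise field
would be split at its mean and the estimate biased high by
`sd·√(2/π) ≈ 2.4` at sd 3. Fewer than 10 % background candidates is an
error ("field too crowded").

Foreground pixels must sit more than `min_deficit = 10` below the background
in *every* band — every object class is darker than background in all bands,
and 10 sits below the faintest printed deficit (15). Components are
8-connected; touching objects merge into one region, the same convention the
area-ratio counter expects for conjugate clusters. The size floor defaults
to the area of a 2 µm disk at the current pixel scale. Object selection is
automatic; the original workflow picked ≥ 20 cells by hand, and the ≥ 20
floor survives as the default `min_n` of `summarize_differences`.

For phone images, where single cells are unresolvable, the conjugate-complex
area is identified differently (`largest_dark_region`): a global Otsu split
of luminance, keeping the largest dark component. A fixed absolute deficit
floor would gate the stained and undyed images at the same darkness and
suppress the very contrast being measured; the global split follows
"separate the complex from the rest of the image" instead.

## Color analysis

`band_differences` is exact signed subtraction (no clamping), so it is
affine in the object mean. Classification is two-stage: objects whose
smallest deficit is under `stage1_min_deficit = 10` are background; stage 2
accepts classes whose per-band intervals contain the observed deficits and
assigns the nearest class centre in Euclidean d-space. The bundled intervals
are midpoints between adjacent class deficits per band — a calibration
derived from the class profiles, not a measured constant; rule validation
rejects tables whose own centres do not round-trip. Class profiles are
treated as class means (of the ≥ 20-cell averaging), not per-cell values.

The mobile statistic is the per-band relative change
`100·(I_ref − I_sample)/I_ref` between complex areas of matched undyed and
stained phone images; when the reference is the background itself this
reduces to `d/background`. `concentration_trend` checks that deficits fall
strictly as the stain is diluted and reports the most
concentration-sensitive band.

## Quantification

`estimated_count = Σ area / mean_cell_area`. "Total cell area" is read as
the *average single-cell* area in the denominator: the reported focal-plane
values (8070 … 95, 7036 … 77) behave as cell counts, and the detection floor
is quoted as "~77 cells". The single-cell average excludes regions larger
than 1.6× the median region area (two merged cells roughly double the area).
Density bounds are strict on both sides, so exact boundary counts
(30,000 / 50,000) fall to the lower class; the ultra-low bound (default
1,000) is a configurable addition for near-floor regimes. Efficiency is
computed on estimated counts rather than raw areas so first/last images need
not share magnification; reports carry the pixel scale to make mismatches
visible, and efficiencies above 100 % are flagged, never clamped.
`linearity_check` is an ordinary least-squares fit with a configurable
r² ≥ 0.95 verdict.

## Synthetic fixtures and what passing means

- **Compartment pairs** (`make_compartment_pair`): last-compartment count =
  `round(first·(1 − loss))`, bead content preserved. Density presets render
  300 / 200 / 120 / 95 cells — scaled-down focal-plane equivalents chosen so
  scenes stay non-overlapping; the ultra-low preset keeps the true ~95-cell
  floor regime. At 19 % loss the ultra-low pair is exactly 95 → 77 cells.
- **Mobile piles** (`make_mobile_pair`): 300 conjugates in one dense
  Gaussian clump (sigma = 6 object radii, ~180 µm across) rendered at 4×,
  then phone-resampled with matched geometry between the undyed and stained
  versions.

The generator emulates the *statistics* the pipeline consumes — background
level and noise, per-class deficits, object sizes, cluster stacking,
resolution loss — not real optics: no debris, no illumination gradients, no
white-balance or exposure variation between devices, no partially stained
cells, uniform disks instead of textured cells. Tests passing on these
fixtures show the measurement chain is correct and calibrated to the class
profiles; they do not show robustness to those unmodelled real-image
effects.

## Numerical choices and problem sizes

Images are uint8 with rendering in float and a single round-and-clip at the
end. The default test fields are 768×1024 px (some stability tests use
512×512), chosen so every suite fixture renders in well under a second while
holding up to a few hundred non-overlapping cells. Recovery fixtures use
100 objects per class; the noisy-class tolerance (±3 intensity units) covers
the small positive selection bias (~+1) the foreground criterion introduces
for the faint unstained class by dropping its lowest-deficit edge pixels.
Classification ties (equal Euclidean distance) resolve to the
alphabetically first candidate; dominant-band ties resolve R > G > B and are
flagged.

## Known limitations

- The area-ratio counter assumes one focal plane and monodisperse cells; a
  mixed-size population biases the single-cell denominator.
- Transmittance stacking ignores scattering and saturation, so very deep
  piles darken faster than real ones.
- Thresholds are calibrated to the bundled profiles; other stains, exposure
  settings or white balances need a recalibrated rule table (the YAML config
  is the place).
- No watershed splitting: touching cells count by area, not by instance.
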