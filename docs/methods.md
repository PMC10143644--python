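# Methods

## Radiometric model and calibration

A hypercube is a `[band, row, col]` array on a uniform ascending wavelength
grid; the default grid runs 650–820 nm at 2.5 nm spacing (69 bands),
matching a VIS/NIR snapshot camera. Units move through an explicit state
machine, `DN → radiance → reflectance`, and operations reject cubes in the
wrong state. The DN→radiance step is a per-band affine model
(`radiance = gain·DN + offset`); no dark-current or flat-field modelling
beyond that.

Reflectance is the per-band ratio of scene radiance to the mean radiance
over the white Lambertian reference panel's ROI. The mean (not median) is
used because the panel is spatially uniform and the noise model additive
Gaussian, making the mean the efficient estimator. The bare ratio maps the
panel itself to 1; since the physical panel reflects 75%, the default
(`apply_panel_scale=True`) multiplies by the nominal 0.75 so the panel maps
to its true reflectance. Both behaviours are exposed because field practice
varies; the choice rescales every spectrum by a constant and therefore
cannot change any slope-based comparison, ANOVA outcome or regression r².
Calibration is scale-equivariant: multiplying the radiance cube by any
constant (illuminant strength) leaves reflectance unchanged, which the
generator exercises by rendering under a smooth non-flat illuminant.

Panel ROIs are supplied by configuration, not auto-detected: on conveyor
platforms the panel position is fixed per session. Coordinates are 0-based
with half-open rectangles.

## Segmentation

Plants sit against a matt black background, so on a high-NIR band the
brightest pixels are leaf regions facing the camera under direct
illumination. Segmentation:

1. **Crop the panel**: keep the largest of the four rectangles (left,
   right, above, below the panel ROI) — the percentile must be computed
   without the bright panel or it would absorb most of the top ranks.
2. **Threshold one band** (default 750 nm, the top of the red edge): the
   nearest-rank percentile (value at rank ⌈p·n/100⌉ of the sorted frame,
   default p = 96) with **strict** inequality for selection. Nearest-rank +
   strict reproduces the exact "top 4%" on all-distinct frames and makes
   the mask invariant under any strictly monotone transform of the band
   image.
3. **Propagate** the one-band binary mask to all bands and store only the
   selected spectra (coordinate list + per-band values in a compressed
   container; dense reconstruction available).

Two degenerate regimes are handled explicitly. A constant (or exactly
noiseless, hence heavily tied) frame puts the threshold on the plateau
value itself and the strict inequality selects nothing: this returns an
empty mask with an `EmptyMaskWarning` rather than guessing a tie-break.
And when the plant occupies less than the retained top fraction of the
cropped frame, bright background can leak into the mask; a plausibility
guard warns when the masked mean reflectance at 650 nm exceeds a bound
(default 0.5 — vegetation is dark in the red).

Storage accounting compares the serialized compressed sizes of the dense
cube and the sparse store; `reduction_pct = 100·(1 − after/before)`.

## The H-index

From the masked cube, the mean signature (per-band mean and sample SD over
selected pixels) is computed first, then differenced — average-then-
differentiate, which suppresses pixel noise before the derivative. The
H-index is the maximum first difference, divided by the band spacing by
default (units reflectance·nm⁻¹); a flag restores the raw per-band
difference, which differs only by the constant spacing on a uniform grid
and cannot alter any comparison. Ties between equal maximal slopes go to
the shorter wavelength, and the reported `lambda_max_slope` is the midpoint
of the maximizing band pair.

Properties relied on (and tested): linearity under signature scaling,
invariance under additive offsets, equality with a brute-force maximum over
adjacent pairs, and invariance under small spectral shifts of
interior-maximum curves — the practical argument for a slope index on
cameras with thermal wavelength drift. A shift large enough to push the
maximizing pair across the array edge breaks the invariance; the
`shift_invariance_check` helper makes that caveat measurable. No smoothing
is applied before differencing (an optional moving average exists but is
off); no model-inversion red-edge position estimators are provided — the
point-by-point derivative is the method.

For a logistic red edge with plateaus `r_red`, `r_nir`, inflection
`λ_i` and steepness `rate`, the analytic maximum slope is
`(r_nir − r_red)·rate/4` at `λ_i`; on the 69-band grid the H-index recovers
the inflection within one band spacing and the slope within 5%
(discretization bias of sampling a smooth maximum at 2.5 nm).

## Optical indices

RGB segmentation is a hue-range + brightness rule: plant pixels have hue in
[60°, 180°) on the standard HSV wheel and HSV value above a dark-background
cutoff (default 0.15). Hue convention: standard wheel, green = 120°,
yellow = 60°; the senescence bands only make sense on it.

- **PSA** = (|TV| + |SV0| + |SV90|) · px_area_cm2. The cm²-per-pixel factor
  is a required calibration input.
- **HUE** = arithmetic mean hue of plant pixels (pixel-weighted across
  views). Arithmetic, not circular: leaf hues live in 60–180°, far from the
  wrap point.
- **SI** = (GAS − GerAS)/GAS per side view, averaged over SV0 and SV90,
  with GAS the **count** of masked pixels with hue in [60°, 180°) and
  GerAS the count in [80°, 180°) (intervals closed-left, open-right).
  Counts, not summed hue values: GAS is an area and SI a fraction, and the
  nesting of the bands guarantees SI ∈ [0, 1]. GAS = 0 raises a dedicated
  error, distinct from SI = 0.

## ET and VPD

Daily ET per pot is the morning-to-morning weight difference corrected for
water restored after weighing: `ET_d = (TW_d + added_d) − TW_{d+1}` grams.
Weighing-before-watering is the assumed convention (configurable by simply
omitting the `water_added_g` column). Negative ET values (balance noise)
are retained with a warning rather than clipped, so the telescoping
identity `Σ plain ET = first − last weight` holds exactly.

Saturation vapour pressure uses the Tetens form
`es = 0.6108·exp(17.27·T/(T + 237.3))` kPa, valid for greenhouse
temperatures; `ea = es·RH/100` with the concurrent RH (no dewpoint sensor
is assumed). Daily VPD takes the records at the day's maximum and minimum
temperature and averages the two instantaneous deficits — a two-point
scheme that tracks the nonlinearity of es better than evaluating at the
mean temperature.

## Statistics

One comparison per genotype × phase × index: a classical one-way ANOVA of
stressed vs control replicates, flagged at α = 0.05. No multiple-testing
correction by default (per-comparison testing is the platform convention
for these small designed grids); a Bonferroni option exists. Degenerate
cells are flagged, not silently dropped: zero within-group variance with
equal means is a 0/0; with unequal means F = ∞, p = 0 with its own flag;
cells missing a treatment or with fewer than 2 replicates are reported with
status `missing`. Each optical index is regressed against the H-index by
OLS (slope, intercept, r²).

## Synthetic scenes: what they emulate and what they do not

The generator reproduces the statistical structure the analysis assumes:

- **Spectra**: logistic red edge, defaults `r_red = 0.05`, `r_nir = 0.50`,
  `λ_i = 715 nm`, `rate = 0.08 nm⁻¹` (healthy-leaf scale values; the
  experiment they stand in for published no leaf-spectrum parameters, so
  these are design choices, not estimates). Additive Gaussian band noise
  (default SD 0.01 reflectance) truncated to [0, 1].
- **Stress encoding**: `rate` and `r_nir` are scaled by `(1 − stress_level)`
  — drought flattens the red edge — so the H-index is, by construction,
  strictly decreasing in stress on noiseless scenes. `stress_level` is the
  fractional attenuation itself; a level of 0.155 cuts the analytic maximum
  slope by 30%.
- **Scene geometry**: flat 75% panel, flat dark background (default 0.05),
  a compact plant blob (default 12% of the frame) split into illuminated
  pixels and shaded pixels (default 35%) whose spectrum is the same shape
  times a factor drawn from (0.35, 0.75). Multiplicative shading is what
  makes one-band percentile selection pick only illuminated pixels — the
  property the segmentation tests verify against ground truth.
- **RGB views**: per-view plant blobs whose areas shrink with stress and
  vary between replicates (CV 6%); plant hue ~ Normal(120° − 60°·senescence,
  12°) clipped to [60°, 180°]; near-black background. In the full
  experiment, senescence progresses linearly over the season and is pushed
  further by stress.
- **Experiment**: 4 genotypes × 2 treatments × 6 replicates, five
  acquisitions (baseline + ends of stress I / recovery I / stress II /
  recovery II, spanning 27 May – 22 June), per-genotype stress effects
  (defaults 0.45, 0.45, 0.30, 0.30 — two susceptible, two tolerant), stress
  relaxing to 0 in recovery. Replicate-level biology: rate and r_nir vary
  with CV 5% and the inflection with SD 2 nm between pots.
- **Weights**: control pots get 100% of the day's loss restored, stressed
  pots 70% during deficit windows; stressed plants also transpire less
  (factor 0.7), so measured ET separates treatments. Pots re-wet to
  capacity at recovery onset.
- **Weather**: 15-min records, sinusoidal diurnal cycle (T peak 15:00, RH
  anti-phase), slow seasonal warming, mild noise; daily VPD lands in a
  1–2.3 kPa greenhouse envelope.

Not emulated: radiative-transfer realism (no PROSPECT/SAIL), 3D canopy
geometry, specular effects, absolute radiance levels, spatial noise
correlation, or camera spectral response functions. Passing tests therefore
demonstrate that the algorithms recover what they are defined to recover
under the assumed scene structure — not that the defaults match any
particular crop's optics.

## Problem sizes and reproducibility

Tests and the parameter-recovery suite run at desk scale: 48–64-pixel
frames (the generator is configured up to the camera-native 1024×1024,
exercised only for bookkeeping), 2–4 genotypes × 2–6 replicates, 200
simulated experiments for the power and type-I calibration runs. Power is
assessed at the weakest effect the claim covers (exactly a 30% slope
reduction) through the complete cube → calibration → segmentation →
signature → H-index → ANOVA path. Every stochastic component draws from an
explicit `numpy` Generator seeded from configuration; pipeline outputs are
a pure function of (manifest, config), and rerunning with the same seed
reproduces every file byte for byte.

## Known limitations

- The percentile mask needs the plant to occupy more than the retained top
  fraction of the cropped frame; smaller plants let bright background in
  (the red-band guard only warns).
- SI is undefined (not zero) when no pixel falls in the green band; callers
  must handle the dedicated error.
- The ANOVA assumes within-cell normality; the H-index of a pot is a
  maximum statistic and is only approximately normal across replicates.
  With n = 6 per group the F-test is robust to this in the calibration
  runs, but heavy-tailed biological variation would warrant a rank test.
- ENVI support covers the plain header + raw interleaved layout (BSQ / BIL
  / BIP, float and integer types), not vendor-proprietary raw formats.
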