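# Methods

## Measurement model

Hyperspectral core scans are treated as cubes `(row, col, band)` on a shared
wavelength axis; rows run downcore (row 0 = core top, depth at the pixel
centre, default pixel size 80 µm). Raw counts are scaled to reflectance with
`R = (raw − dark)/(white − dark)`, where the white frame approximates total
reflectance and the dark frame (closed aperture) total absorbance. Values
outside [0, 1] — possible under sensor noise — are clipped; the scaling is
invariant to adding a common offset to all three frames. Any band where the
white reference does not exceed the dark reference is rejected with a
band-identifying error.

## Continuum removal

The continuum is the upper convex hull of the spectrum, computed with a
monotone-chain sweep over (wavelength, reflectance) points; collinear runs
collapse to their endpoints, which leaves the interpolated hull unchanged.
The hull is fitted over a configurable window, default 550–850 nm, rather
than the full 400–1000 nm range: the trough region of interest lies well
inside it and the VNIR edge bands are the noisiest part of pushbroom
spectra. Outside the window the hull is defined to equal the spectrum, so
the continuum-removed value there is exactly 1 and removal is idempotent
everywhere. Removal rejects non-positive reflectance inside the window.

The hull has an exact independent characterisation used in the tests: its
value at a band equals the maximum over all chords between point pairs
spanning that band (every chord between points on or below a concave
function lies below it). The fast hull matches this O(n²) oracle to < 1e-9
on random spectra and matches the upper chain extracted from
`scipy.spatial.ConvexHull`.

## Band-depth and band-area indices

`RABD` evaluates the local two-point continuum at the trough minimum band
and divides by the reflectance there:

    RABD_min = ((X_right·R_left + X_left·R_right)/(X_right + X_left)) / R_min

Wavelengths snap to the nearest band centre (ties to the lower band);
`X_left`/`X_right` are the band-step counts between snapped indices. RABD is
computed on calibrated reflectance, not on continuum-removed spectra — the
formula already embeds its own local continuum; full continuum removal is
used for spectral display and QC. By default the minimum band is fixed at
the profile centre; a `float_min` flag lets it float to the deepest band
between the shoulders.

`RABA` sums the relative deficit `(C_i − R_i)/C_i` below the shoulder chord
`C` across the window. Normalizing each deficit by the chord makes the area
scale-free (multiplying the spectrum by a constant leaves it unchanged),
which keeps the index comparable across sediments of different brightness.

Default profiles: RABD620 = 600/620/640 nm (phycocyanin), RABD675 =
650/673/700 nm (chlorophyll *a*), RABD660 = 650/660/690 nm (total chlorins,
downcore use), RABD845 = 800/845/880 nm (bacteriopheophytin *a*). The PC and
chlorin windows share no band — a conservative choice that underestimates
absolute trough depth but guarantees RABD620 is a pure PC signal. Whether
the downcore chlorin profile should share the 671–675 nm trough of the
methods profiles is genuinely open; both ship.

Per-pixel maps are computed first and ROI statistics second (arithmetic mean
over finite pixels). Pixel-first and mean-spectrum-first orders agree only
on homogeneous cubes; because `1/R_min` is convex, the pixel-first mean
exceeds the mean-spectrum index on heterogeneous cubes (Jensen), and a test
documents the inequality. Spike series are normalized by the unspiked
(mass 0) index, making step 0 exactly 1 and removing matrix-level offsets.

## Calibration statistics

Calibration lines are ordinary least squares with R² and a two-sided
*t*-test on the slope (n − 2 degrees of freedom, no multiple-testing
correction). RMSEP uses k-fold cross-validation (default tenfold) with fold
membership from a seeded shuffle; pairs are canonicalised by sort order
first, so the estimate is invariant to reordering the input. RMSEP is
expressed as a percentage of the mean observed response; range- or
max-based denominators can be obtained by rescaling but the mean is the
package convention. When n < folds the fold count silently degrades to
leave-one-out with a warning (e.g. n = 4 spike series). The Bennett–Bogorad
phycocyanin equation is implemented as
`PC = (A620 − 0.474·A652)/5.34 mg/ml` with both coefficients exposed as
arguments; negative concentrations floor at 0 with a warning.

## Synthetic data generator

The generator emulates pigment-spiking experiments: known pigment masses
added stepwise to sediment aliquots which are rescanned after each step.

* **Backgrounds.** Each matrix class (organic, clastic, dried CRM) has a
  smooth background continuum, PCHIP-interpolated through knots sampled from
  a concave, monotonically rising reflectance curve (dark organic ≈
  0.12–0.40, clastic ≈ 0.25–0.60, bright CRM ≈ 0.35–0.70). Concavity makes
  the unspiked baseline its own convex hull, so continuum removal of clean
  sediment is exactly 1 — no spurious troughs.
* **Troughs.** Absorbance is Gaussian per pigment, centred at 620/673/845 nm
  with σ = 12/10/15 nm, amplitude `sensitivity · visible_fraction · mass`.
  Reflectance couples as `R = R_bg · 10^(−A)` (transmittance convention),
  clipped to (0, 1]. Sensitivities default to 0.002 (PC), 0.0175 (Chl *a*)
  and 0.002 (Bphe *a*) absorbance units/µg, chosen so that 150 µg PC gives a
  ≈ 0.5 continuum-removed trough depth and 20 µg Chl *a* ≈ 0.55 — the
  qualitative depth scale of real spiked sediments; only directions, never
  these magnitudes, are asserted anywhere. Matrix classes differ in
  sensitivity (clastic damped, CRM steepest) to encode the matrix effect.
* **Noise.** i.i.d. Gaussian per pixel per band (default sd 0.01 reflectance
  units, CRM 0.006, clastic 0.012); the real instrument's noise structure is
  not modelled. `visible_fraction` (default 1) scales the optically visible
  share of a spike; pore infiltration is not mechanistically modelled.
* **Spectrophotometer series.** `A = α·L·c` exactly at zero noise
  (α = 88.15 l g⁻¹ cm⁻¹ for chlorophyll *a* in acetone), with optional
  Gaussian absorbance noise.
* **Determinism.** All randomness flows through explicit
  `numpy.random.default_rng(seed)` instances; identical (spec, plan, seed)
  give bit-identical cubes.

What passing tests on this generator do **not** show about real sediments:
wet-sediment radiative transfer, pigment–matrix chemistry, porosity and
water-content effects, spatially correlated instrument noise and
white-reference drift are all absent, so quantitative slopes here say
nothing about field calibrations — the generator validates the measurement
operators and the qualitative findings (monotone response, chlorophyll
masking), not absolute sensitivities.

## Interference analysis

Fixed-PC series (default PC = 150 µg, Chl *a* 0–20 µg in 5 µg steps) yield
per-step ROI means of RABD620 and RABD675. The masking curve pairs the
Chl *a*/PC mass ratio with the RABD620/RABD675 index ratio and reports
Spearman ρ. The interference regression fits RABD620 on Chl *a* mass; under
trough overlap the slope is negative because the chlorophyll shoulder lowers
the 640 nm endpoint of the PC window and with it the local continuum. Pass
criteria are sign-based: magnitudes depend on the generator's sensitivity
scale. One subtlety: the slope magnitude is not monotone in the chlorophyll
trough width, because a very wide trough (σ ≳ 40 nm) also depresses the
620 nm minimum band, which raises RABD620 and partially cancels the
shoulder effect; the width comparison is therefore tested in the
shoulder-dominated regime (σ = 10 vs 25 nm).

"Trough disappearance" for the detectability threshold is operationalised as
loss of any local minimum of the noiseless continuum-removed spectrum inside
the PC window (600–640 nm); the threshold is the smallest Chl *a* mass on a
grid at which that happens, or "not reached".

## Pipeline, formats, problem sizes

The end-to-end runner (simulate → indices → calibration → interference →
downcore) is driven by one YAML/JSON config and one seed; config violations
are reported field-by-field before any computation, CSV outputs have fixed
column order and are byte-stable for a given seed, and a manifest records
the config hash, seed and package version. Cubes round-trip through a
generic ENVI dialect (ASCII `.hdr` + flat binary, bsq/bil/bip, float32/64,
wavelengths written at full double precision so the axis survives
bit-exactly).

Default problem sizes — 16×16-pixel cubes on a 301-band axis, 500-seed
slope-recovery and 1000-seed type-I-error simulations — keep the full test
suite and the acceptance script in the seconds-to-minutes range while
leaving every statistical check comfortably powered.

## Known limitations

No spectral deconvolution of overlapping troughs, no correction algorithm
for chlorophyll interference, no carotenoid indices, no geometric
calibration or mosaicking, no age–depth modelling. The Bennett–Bogorad
coefficients follow the standard published equation and should be replaced
if a laboratory uses a different extract convention.
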