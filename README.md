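# phycospec

In-situ hyperspectral detection and relative quantification of **phycocyanin
(PC)** — the blue phycobiliprotein marker pigment of cyanobacteria — in lake
sediment cores, together with its chlorin counterparts (chlorophyll *a*,
bacteriopheophytin *a*).

Hyperspectral core scanners record VNIR (400–1000 nm) reflectance at
sub-millimetre pixel size. Sedimentary pigments appear as absorption troughs
in these spectra: PC near 620 nm, chlorophyll *a* near 660–675 nm,
bacteriopheophytin *a* near 845 nm. `phycospec` provides the full measurement
chain for paleolimnologists who want downcore cyanobacteria proxies from such
scans, plus a synthetic spiking-experiment generator with known ground truth
to validate every step.

## What it computes

**Reflectance calibration.** Raw counts are scaled to 0–1 reflectance with a
white (BaSO₄) and a dark (closed-aperture) reference:
`R = (raw − dark) / (white − dark)`.

**Continuum removal.** Each spectrum is divided by its upper convex hull
(straight segments over the local maxima), so absorption features become
deviations below 1.

**Relative Absorbance Band Depth (RABD).** For a trough with left/right
shoulder bands and a minimum band,

```
RABD_min = ((X_right · R_left + X_left · R_right) / (X_right + X_left)) / R_min
```

where `X_left`/`X_right` count band steps from the shoulders to the minimum
and `R` are reflectances at the snapped bands. A flat spectrum gives exactly
1; a deeper trough gives a larger value. The shipped profiles are
conservative and non-overlapping — `RABD620` uses 600/620/640 nm, `RABD675`
uses 650/673/700 nm — so the PC index is never a mixed signal with
chlorophyll. The companion band-area index (RABA) integrates the relative
reflectance deficit below the shoulder chord.

**Calibration statistics.** Beer–Lambert conversion (`A = α·L·c`), the
Bennett–Bogorad spectrophotometric PC equation, OLS calibration lines with
R² and slope *t*-test p-values, and tenfold cross-validated RMSEP (% of the
mean response).

**Interference analysis.** Chlorophyll *a* absorbs strongly and its trough
shoulder reaches into the PC window, masking the PC trough: the package
quantifies the RABD620 decline under Chl *a* spiking at fixed PC, the
masking curve of RABD620/RABD675 against the Chl *a*/PC mass ratio, and a
detectability threshold where the 620 nm local minimum vanishes.

**Synthetic spiking experiments.** Three sediment matrix classes (organic,
clastic, dried CRM) with smooth concave background continua, Gaussian
absorption troughs whose depth responds linearly to spiked pigment mass with
matrix-specific sensitivity, per-pixel Gaussian noise, and explicit seeds for
bit-exact reproducibility.

## Worked example

```python
import phycospec as ps

spec = ps.MATRIX_SPECS["organic"]
plan = ps.SpikePlan("PC", (0.0, 50.0, 100.0, 150.0))
cubes, truth = ps.simulate_spiking_cubes(spec, plan, shape=(16, 16), seed=42)
for mass, cube in zip(plan.masses_ug, cubes):
    value = ps.roi_mean(ps.index_map(cube, ps.TROUGH_PROFILES["RABD620"]))
    print(f"{mass:>5.0f} ug PC  ->  RABD620 = {value:.4f}")
```

prints

```
    0 ug PC  ->  RABD620 = 0.9985
   50 ug PC  ->  RABD620 = 1.1933
  100 ug PC  ->  RABD620 = 1.4079
  150 ug PC  ->  RABD620 = 1.6774
```

The unspiked sediment sits at ~1 (no trough); the index rises monotonically
with the spiked PC mass because the 620 nm trough deepens proportionally.
Normalizing by the unspiked value and regressing on mass gives the
calibration line (R², p-value, RMSEP%) via
`ps.build_calibration_report(...)`. The `examples/` directory holds one
short narrative script per capability (simulation, continuum removal and
indices, calibration, interference, downcore profiles); each prints the
numbers it computes and what they mean. A thin CLI mirrors the library:
`phycospec simulate | calibrate-reflectance | indices | calibrate |
interfere | downcore | run`.

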