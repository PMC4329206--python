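# Methods

## Forward model

The simulator replaces the instrument with a linear magnetostatic chain.

**Excitation.**  The excitation coil is a single circular loop of radius
`excitation_radius` (default 30 mm) in the probe's bottom plane, with its
field normalised so the centre value equals `excitation_center_field`
(120 Oe).  Off axis the field is evaluated with the elliptic-integral
closed form of the circular-loop Biot–Savart field; on axis this reduces to
`H0 a³/(a²+z²)^{3/2}`, and beyond ten radii it obeys the dipole `H z³ =
const` scaling.  The 400 Hz excitation frequency is carried as metadata
only: demodulation is not simulated, and the lock-in output is modelled as
the in-phase amplitude directly.  This is exact for a purely
susceptibility-driven response; remanence and Brownian/Néel relaxation are
outside the model.

**Sources.**  A scene is a set of point-dipole voxels; each voxel's
`magnetism` (emu) is the moment it exhibits under the reference 120 Oe
field, and its effective moment scales linearly with the local excitation
amplitude (low-field AC susceptibility).  Moments are oriented axially,
like the excitation.  Voxelisation conserves total magnetism exactly (equal
shares per voxel).  1 emu = 10⁻³ A·m².

**Pickup.**  The gradiometer is two coaxial loops of radius `pickup_radius`
(10 mm) at `pickup_offset` (5 mm) and `pickup_offset +
gradiometer_baseline` (55 mm) above the probe's bottom plane, wound in
opposition.  The flux of each dipole through each loop is computed by
surface quadrature over the loop disk (Gauss–Legendre radial × uniform
angular; the public single-dipole path doubles the resolution adaptively
until successive values agree to 1e-8 relative and raises on
non-convergence).  The field-equivalent signal is the flux difference over
the loop area; tests check the quadrature against a 10×-finer brute-force
grid and against the closed-form reciprocity route (loop field at the
dipole), and check exact superposition.

**Readout.**  Signal in Volt = `volt_per_tesla × transfer_gain ×`
field-equivalent signal, with `transfer_gain` = 29.  The instrument's
absolute Volt calibration is not published, so `volt_per_tesla` defaults to
a pure display calibration: the reference phantom (0.075 emu of reagent at
31 mm standoff, scanned at the default coverage) peaks at exactly 1.0 Volt
in the baseline-corrected image.  Every quantitative claim in the package
therefore rests on shapes, ratios and orderings, never on absolute Volts.
Noise is white and field-equivalent, `noise_density` = 3 pT/√Hz, integrated
over the per-pixel equivalent noise bandwidth 1/(2·dwell); a dwell of one
step at scan speed (1 s at defaults) gives σ ≈ 1.4 µV on the display scale.
All noisy paths require a seeded generator and record the seed.

## Scan geometry and images

Scans are rasters of lines along x (5 mm step = pixel size, 5 mm line
interval, 5 mm/s).  Each pixel is one probe signal — in the noiseless model
the value is independent of speed, so scanning and static acquisition
coincide; speed only sets the noise bandwidth.  Per line, the free-space
baseline — the mean of the first and last samples — is subtracted (a
first→last linear-drift variant is available behind a flag; whether the
real system used the start, the end, or both is unknowable from the outside,
and the both-ends mean is the symmetric choice).  Baseline correction is
invariant to any per-line additive offset.

Line ends must be genuinely signal-free for the baseline to mean anything.
Because the gradiometer response half-width is comparable to the source
depth (~15 mm at 31 mm standoff, ~25 mm at 66 mm), the default coverage
places line ends 45 mm outside the scene support (the hard floor any plan
must meet is 10 mm); across track the coverage extends 30 mm so half-max
masks close inside the image.  With 10 mm ends the baseline would absorb up
to ~25 % of the peak at the deepest standoff.

The optical mosaic stacks per-line panorama strips, each cropped to its
central 2/3 across track (panorama edges are distorted); the retained band
must tile the line interval exactly.  With a 5 mm line interval this forces
the optical pixel to 0.5 mm/px (15 px strips, 10 px retained) — finer than
the magnetic grid, so contour agreement is meaningfully sub-magnetic-pixel.
Both images share one mm frame with pixel-centre coordinates; registration
is trivial by construction, as in the instrument.

## Quantification

Spots are 8-connected components (diagonal ridge continuity at 5 mm pixels;
4-connectivity available) above `k_sigma` (default 3) times the free-space
noise estimate, taken from the line-end pixels (their post-correction
variance is σ²/2, hence the √2 factor) or supplied analytically.  For a
noiseless image the level is zero and any strictly positive pixel is
suprathreshold.

Per spot, the half-max filter keeps pixels with `I ≥ 0.5 I_max` **of that
spot** — the ≥ rule keeps a one-pixel spot's peak and includes
exact-boundary pixels (a plateau exactly at the level is enclosed).  The
integral of I multiplies the retained sum by the pixel *area* (25 mm²), so
the units are the printed Volt·mm²; the literal sum-times-spacing variant
(Volt·mm) sits behind a flag, as does a plain (unfiltered-sum) total for
the before/after comparison statistic.  Sub-pixel half-max contours come
from marching squares with bilinear interpolation, restricted to the spot's
own neighbourhood.

Contour agreement is reported as both the symmetric mean boundary distance
and the symmetric Hausdorff distance over boundaries densely resampled at
≤0.5 mm; the Hausdorff value is the conservative headline, since the
original "spatial error" metric is not named.

## Classification

A region of interest is positive when the integral of I restricted to it
(filtered pixels whose centres fall inside the polygon; centre membership
makes disjoint ROIs partition the image total exactly) reaches
0.10 Volt·mm².  A tie is called positive — clinical conservatism.
Concordance against ground-truth labels is plain accuracy with a 2×2
confusion table.  `roc_optimal_threshold` recovers the accuracy-maximising
cut from data, using geometric midpoints (the statistic spreads
multiplicatively) and returning the geometric mean of the optimal
candidates.

## Synthetic scenes

The generators define the study conditions:

* **Phantoms** — cylinders of 0.25 g reagent (unit density) in a 6 mm tube
  (any diameter < 8 mm is accepted), at 0.005–0.3 emu/g and 31–66 mm
  standoff, 1 mm voxels.  Ground truth is the tube's top-view circle.
* **Animal scenes** — a schematic body ellipse carrying one 5 mm-voxel
  tissue layer at 35 mm depth with 3×10⁻⁷ emu per voxel of weak
  paramagnetic background (red blood cells etc.); this level is set so the
  pre-injection (0 h) total integral is ~10 % of the 24 h value.  A liver
  is five convex lobes in a fan (biological realism is explicitly not
  attempted); at 24 h each labelled-positive lobe receives an uptake blob
  of 1.5×10⁻⁴ emu (~0.06 % of the injected 0.27 emu dose) at 32 mm depth
  with seeded placement jitter.  These uptake/background defaults are
  modelling choices pinned to the display calibration — chosen so positive
  separated lobes integrate at ~0.6–0.75 Volt·mm² (above 0.10) and negative
  ones near zero — not measurements.  Uptake is uniform within a blob; the
  true spatial pattern of hepatic uptake is unknown.
* **Separated lobes (ex vivo)** — per-lobe quantification follows the ex
  vivo protocol: the lobes are re-laid side by side, 55 mm apart, at one
  common 32 mm standoff.  In situ the gradiometer response width (~ source
  depth) makes adjacent fan lobes bleed into each other and stacked lobes
  sit at unequal depths; separation removes both confounds, which is
  precisely why the wet-lab protocol separates the lobes before staining.
* **Lobe statistics** — `make_lobe_dataset` draws per-lobe integrals from
  lognormals centred at `0.10·e^{±separation/2}` with log-sd `sigma`
  (defaults 1.0 and 0.25: modest overlap; `separation → ∞` is perfectly
  separable, 0 is chance).
* **Panoramas** — strips rendering the ground-truth contours (brown tube
  circle, blue dashed tumor outline, grey lobe edges) on a light
  background, 1.5 line intervals wide so the central-2/3 crop tiles the
  swath.

## Experiments and problem sizes

`run_phantom_experiment` sweeps the five study concentrations × eight
standoffs (31–66 mm in 5 mm steps).  The noiseless chain is exactly linear
in scene magnetism, so one image per distance is simulated at the reference
concentration and rescaled — the spot analysis still runs per
concentration.  Detectability uses `I_max ≥ k_sigma ×` noise σ (the
criterion is stated in the report header since none is defined upstream);
the detectable distance per concentration is found by bisection on the
strictly decreasing peak signal.  `run_animal_experiment` simulates the 0 h
and 24 h in-vivo scans, fuses each with the optical mosaic, then runs the
separated-lobe quantification and the 0.10 Volt·mm² calls.  Noisy replicate
studies re-run the readout on fresh noise draws over one noiseless
simulation (noise is additive), which keeps 50-replicate studies cheap.
Reports are deterministic under a fixed config and seed; configs round-trip
through YAML and every output sidecar embeds the config hash, seed and
version.

## Numerical choices

* Disk quadrature base resolution 20 radial × 32 angular points; the
  adaptive path doubles until 1e-8 relative agreement (error on failure).
* Marching-squares level is set marginally below 0.5·I_max so
  exact-boundary plateaus fall inside the contour, matching the ≥ filter.
* Spot components: strict `>` against the detection level, so a noiseless
  image's zero background never joins a spot.
* ROI membership by pixel centre; area weighting was rejected as
  over-engineering at 5 mm pixels.
* Ties at the classification threshold go positive (documented above).

## Known limitations and non-goals

* Absolute Volt values (and hence the original detectable distances of
  56/44 mm and the 0.05 Volt·mm² integral floor) are not reproducible: they
  depend on the unpublished coil geometry and lock-in calibration.  The
  package checks shapes, ratios and orderings instead.
* Two printed Fe amounts ("250 µg at 56 mm, 12.5 µg at 44 mm") are not
  consistent with concentration × weight × 6.5 mg/g per emu/g for any
  printed concentration (0.1 emu/g → 162.5 µg, 0.005 → 8.125 µg);
  `fe_mass` implements the product formula and this note records the
  discrepancy.
* No frequency-dependent susceptibility, relaxation, remanence, eddy
  currents, lens distortion, lighting, or real video stitching; no
  pharmacokinetics (uptake levels are static per timepoint); no 3-D source
  reconstruction or deconvolution.
* Passing tests on these generators shows the analysis is correct under
  the stated statistical structure (linear response, uniform-within-blob
  uptake, white noise); it does not by itself validate performance on real
  tissue, where background heterogeneity and probe-tissue geometry are far
  richer.
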