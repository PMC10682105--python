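# Methods

`waterpet` simulates and analyses patient motion in dynamic ¹⁵O-water
cardiac PET myocardial perfusion imaging (MPI). This note documents the
models, the synthetic data they are exercised on, the numerical choices,
and what the package's tests do and do not demonstrate about real data.

## Kinetic model

¹⁵O-water is freely diffusible and metabolically inert, so myocardial
blood flow (MBF) is quantified from tracer washout with a single-tissue
compartment model. For a voxel or region with arterial input C_a(t):

    C_PET(t) = PTF · MBF · (C_a ⊗ e^(−k2·t))(t) + V_A · C_a(t),
    k2 = MBF / p

- **MBF** (mL·min⁻¹·g⁻¹): perfusion; equals the uptake constant K1 for a
  freely diffusible tracer (extraction ≈ 1).
- **PTF** (mL·mL⁻¹, 0–1.2): perfusable tissue fraction, the portion of the
  voxel exchanging water with blood; scales the tissue term.
- **V_A** (unitless, 0–1): arterial blood volume / spillover fraction.
- **p = 0.91 mL·g⁻¹**: tissue–blood water partition coefficient, fixed.

Measured dynamic-PET values are frame *averages*, so the forward model
evaluates the continuous curve on a 0.5-s time base and integrates over
each frame interval (the 5-s early frames under-sample the bolus
otherwise; trapezoidal integration with an end-correction keeps the
convolution second-order accurate).

### Fitting

The model is linear in (PTF·MBF, V_A) once the washout rate k2 is fixed,
so fitting uses the basis-function method: frame-averaged basis curves
B_j = ⟨C_a ⊗ e^(−θ_j t)⟩ are precomputed on a grid of 256 log-spaced θ
values spanning 0.06–6 min⁻¹ (MBF ≈ 0.05–5.5 mL·min⁻¹·g⁻¹), and for each
θ the two linear coefficients are solved by closed-form non-negative
least squares. The θ with minimal residual sum of squares wins.

Numerical choices:

- **Grid density.** 256 points give ≈1.8% spacing, bounding quantization
  of a noise-free fit at ≤0.9%. Single-curve fits (`fit_tac`,
  `OneTissueModel.fit`) additionally refine θ continuously by bounded
  scalar minimization between the winning grid point's neighbours, making
  the noise-free round trip exact to ~10⁻⁵; voxelwise parametric fits
  (`fit_parametric`) use the grid alone, fully vectorised across voxels.
- **Degenerate curves.** All-zero voxels are flagged, not fitted; a fit
  with zero tissue coefficient reports MBF = 0 (no perfusable signal),
  not the meaningless grid rate.
- **Image-derived input.** When only the frame-averaged blood curve is
  available, the continuous input is reconstructed by average-preserving
  interpolation (piecewise-linear knots iterated until the curve's frame
  averages reproduce the measurement). Plain mid-time interpolation clips
  the bolus peak and biases MBF by ≈ +3.5%; the reconstruction reduces
  this to < 0.2%.
- **No delay/dispersion correction** of the input function: the phantom's
  input arrives with known delay, and cavity sampling sees the same curve.

Global MBF is reported both as the voxel mean over the whole myocardium
(primary; robust to unequal territory sizes) and as the mean of the three
territory means.

## Synthetic data

No clinical scans are available, so a digital thorax phantom stands in
for motion-free stress scans. It is deliberately simple where simplicity
is harmless and anatomically explicit where motion artifacts are born —
at the tissue interfaces around the heart.

**Geometry** (3.27-mm isotropic voxels; default 96³ grid, studies run at
64³ with identical mm geometry): the LV is a truncated half-ellipsoid
shell (inner/outer short-axis radii 25/35 mm, long-axis elongation 1.8)
whose long axis is tilted 30° from caudal toward anterior, as in the
thorax. Territories are 120° circumferential sectors (anterior+septal →
LAD, lateral → LCx, inferior → RCA) with the apical cap assigned to LAD,
following the standard coronary-territory convention. Blood pools: LV
cavity, a basal atrial/outflow cylinder, and an RV sphere on the right.

**Surroundings.** Motion artifacts in this tracer arise when a fixed
myocardial ROI samples neighbouring tissue whose time course differs
from myocardium:

- *Lung* (anterior/lateral/superior): 12% of the blood curve. Motion that
  drags lung into an ROI suppresses late activity → apparent faster
  washout → MBF overestimated.
- *Subdiaphragmatic and posterior-mediastinal tissue* (liver, stomach,
  spine): a slow compartment (MBF 0.9, PTF 0.85, V_A 0.2) occupying the
  infero-posterior half-space hugging the epicardium, a posterior slab
  (no lung lies between heart and spine), and a conical diaphragm dome
  rising laterally around the apex (the heart sits in the dome's cardiac
  impression). Its slowly accumulating, non-blood-shaped curve raises
  late activity in contaminated ROIs → apparent slower washout → MBF
  underestimated.
- *Cavity blood* is the arterial curve itself; contamination by it is
  largely absorbed by the model's V_A term and perturbs MBF only mildly.

This asymmetry — lung anterior, slow tissue inferior — reproduces the
canonical artifact pattern of anterior (LAD) overestimation and inferior
(RCA) underestimation for anterior/cranial steps, coughs and creep, with
caudal slides affecting RCA only mildly. The phantom's anatomy was chosen
to realise this mechanism; it is an idealisation, not a patient.

**Input function**: a gamma-variate bolus, C_a = A·(τ/(αβ))^α·e^(α−τ/β)
with delay t0 = 10 s, α = 2.5, β = 4.8 s (peak 12 s after arrival, FWHM
≈ 18 s, typical of an automated injector) plus a recirculation plateau of
15% of the peak with 300-s washout.

**Population**: per-subject global stress MBF is drawn from a lognormal
calibrated to the motion-free cohort the study emulates — median 2.35,
IQR 0.82 mL·min⁻¹·g⁻¹ (µ = ln 2.35, σ = 0.2574) — with multiplicative
territory jitter (σ = 0.15, renormalised so the territory mean equals the
global draw) and per-subject PTF ~ N(0.70, 0.05), V_A ~ N(0.15, 0.03).

**Noise**: additive Gaussian with σ ∝ 1/√(frame duration), matching the
first-order behaviour of reconstructed-PET frame noise; `noise_scale` =
0.03 gives ≈10% voxel-level noise on the 5-s frames and a global-MBF bias
below 1%. Reconstruction physics (attenuation, scatter, resolution
blurring, Poisson counting) is not modelled; radioactive decay is assumed
corrected.

What passing tests therefore show: the *pipeline* (injection →
quantification → correction → statistics) behaves correctly and the
artifact mechanisms present in the phantom behave as in the literature.
What they do not show: absolute agreement with any proprietary clinical
quantification, reader behaviour, or artifacts driven by anatomy the
phantom lacks (papillary muscles, wall-thickness variation, partial
volume from finite resolution, intra-frame motion).

## Motion catalogue

Sixteen trajectories in four families of per-frame rigid translations
(amplitudes 5–20 mm; +x right→left, +y posterior→anterior, +z
caudal→cranial):

| family | variants | pattern |
|---|---|---|
| Stress Agent 1–4 | {10, 20} mm × onset {30, 60} s | sustained step, +y and +z simultaneously |
| Linear Slide 1–4 | {10, 20} mm × onset {0, 60} s | linear −z ramp to full amplitude at the last frame mid-time |
| Peak Cough 1–2 | {10, 20} mm | single frame at the myocardial TAC peak, +y |
| Late Cough 1–4 | {10, 20} mm × {60, 120} s | single frame containing that time, +y |
| Cardiac Creep 1–2 | {5, 10} mm | linear +z ramp from 60 s |

The amplitude-to-onset pairing within each family is this package's
reconstruction: the catalogue's directions, amplitudes, counts and
timings are fixed, but no per-variant table was available, so the full
amplitude × onset grid is used. Ramp trajectories are specified in whole
millimetres per frame — the 1-mm resolution of the correction workflow —
so a ground-truth correction can negate them exactly. No rotations or
intra-frame motion are simulated.

**Resampling.** Injection and correction translate each frame exactly
once from its source image (the single-resample contract: editing a
correction and re-running never accumulates interpolation). The default
interpolator is a quintic B-spline: with trilinear interpolation the
inject-then-correct double resample blurs the high-contrast
myocardium/liver and myocardium/lung interfaces enough to shift oracle-
corrected territorial MBF by up to 3.5% from the motion-free value, while
quintic keeps the worst case at 1.6%. Trilinear (`order=1`) and
nearest-neighbour (`order=0`, exactly invertible for whole-voxel shifts)
remain available.

## Correction models

- `oracle_correction`: componentwise negation of the injected trajectory,
  rounded to 1 mm (the tool's step size).
- `reader_model`: an emulation of imperfect human correction — corrects a
  per-axis fraction α of the true shift on axes exceeding a detection
  threshold (default α = (1.0, 0.5, 0.8) for x/y/z, threshold 5 mm,
  optional seeded 1-mm jitter). The defaults qualitatively mirror the
  conservative, z-dominant corrections human readers produce; they are a
  knob, not a claim about any particular reader.
- `estimate_shifts`: automatic estimation by normalized cross-correlation
  against phase-matched references built from the image itself (mean of
  the first 30 s for bolus frames, mean of the ≥60-s frames for later
  ones, split at 35 s where tracer contrast flips from blood pool to
  myocardium). Correlation is windowed to a cardiac region — the largest
  connected component above 35% of the early-phase mean image's maximum,
  dilated by 4 voxels — because the flat, high-activity abdomen otherwise
  dominates. A coarse FFT integer-voxel peak is refined to 1 mm by
  per-axis coordinate descent.

Residual motion is scored per frame and axis as sign(m)·(m − ĉ), where m
is the injected shift and ĉ the motion implied by the correction;
positive values are undercorrection. Axis summaries are medians over
frames with nonzero injected motion. Because corrections are quantized to
1 mm, residuals for non-integer motions are bounded below by 0.5 mm.

## Study design and statistics

A study run generates a seeded subject population, analyses each subject
motion-free, injects every catalogue motion, and re-analyses uncorrected
and after each correction approach. All territorial analyses use the
motion-free ground-truth masks (the workflow's pre-correction
segmentation is the reference overlay), and the input function is
extracted from the analysed image over the eroded LV-cavity mask — so
motion corrupts the image-derived input exactly as it would in practice.

Approaches: `oracle` (ground truth), `reader_pre` (reader emulation on
every scan), `reader_post` (reader emulation only on scans whose
uncorrected analysis shows a large artifact — a computational emulation
of reviewing quantified results before correcting), `automatic`
(cross-correlation estimation).

Definitions and statistics:

- **Relative deviation**: 100·(MBF_test − MBF_ref)/MBF_ref against the
  subject's motion-free analysis.
- **Large artifact**: |deviation| > 20% in ≥1 coronary territory.
- **Interpretation**: positive (abnormal) iff stress MBF < 2.3
  mL·min⁻¹·g⁻¹; exactly 2.3 is normal. Calls are made per territory,
  globally, and as an any-region aggregate; changes after correction are
  counted as true when the post-correction call matches the motion-free
  one.
- **Heatmaps**: per motion × region (LAD, RCA, LCx, global), the median
  and the single most-deviating subject's deviation over the population,
  plus two-sided Wilcoxon signed-rank p-values (exact for small n, no
  multiple-comparison correction) banded at .05/.005.
- **Bland–Altman**: median difference and 95% limits of agreement
  (mean ± 1.96·SD of post−pre differences).

Study-scale computations (the acceptance script and study-level tests)
run the phantom at 64³ voxels with the same voxel size and mm geometry —
the heart and its surroundings fit with the full 20-mm motion margin, and
results are indistinguishable from the 96³ field of view at a fraction of
the cost.

## Known limitations

- One anatomy for all subjects: only kinetics vary across the population,
  so artifact patterns are more consistent across subjects than in
  patients, and signed-rank tests flag more motion × region cells as
  significant than a heterogeneous cohort would.
- Caudal slides place LV-cavity blood over the inferior wall; since
  cavity blood is collinear with the fitted input function, the V_A term
  absorbs most of it and slides perturb RCA only mildly here, whereas
  anatomies with more slow tissue under the heart show stronger negative
  RCA deviations.
- No partial-volume or resolution modelling: compartments are piecewise
  constant, so interface mixing arises only from motion resampling.
- Reader emulation is a parametric stand-in; human-reader performance
  fractions are outside what this package can reproduce.
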