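# waterpet

Simulation, quantification and frame-by-frame rigid motion correction for
dynamic ¹⁵O-water cardiac PET myocardial perfusion imaging.

¹⁵O-water is the reference tracer for non-invasive quantification of
myocardial blood flow (MBF), but it is not retained in the myocardium:
interpretation rests entirely on kinetic modelling of a 4-minute dynamic
scan, which makes the measurement sensitive to patient motion between
frames. This package is for imaging scientists who want to study that
sensitivity quantitatively: it generates synthetic motion-free dynamic
scans with known ground truth, injects a catalogue of sixteen typical
patient motions (stress-agent reactions, linear slides, coughs, cardiac
creep; 5–20 mm), quantifies MBF before and after frame-by-frame rigid
correction, and computes the evaluation statistics of a full simulated
motion study.

## Model

MBF is quantified with the standard single-tissue-compartment model for
freely diffusible water:

    C_PET(t) = PTF · MBF · (C_a ⊗ e^(−(MBF/p)·t))(t) + V_A · C_a(t)

with perfusable tissue fraction PTF (mL·mL⁻¹), arterial spillover
fraction V_A, partition coefficient p = 0.91 mL·g⁻¹, and arterial input
C_a. Fitting uses the basis-function method (washout rate on a log grid,
non-negative linear least squares per grid point), frame-averaged exactly
as dynamic PET measures it. Scans are read as abnormal when stress MBF
falls below 2.3 mL·min⁻¹·g⁻¹ globally or in a coronary territory
(LAD / RCA / LCx); motion artifacts are relative MBF deviations from the
motion-free analysis, with >20% in a territory counting as large.

See `docs/methods.md` for the phantom anatomy, the motion catalogue, the
correction models and all numerical choices.

## Worked example

```python
import waterpet as wp
from waterpet.study import MotionStudy, DeviationReport

grid = wp.build_frame_grid()                      # 21 frames, 240 s
spec = wp.PhantomSpec(grid_shape=(64, 64, 64), noise_scale=0.0)
image, truth = wp.generate_phantom(spec, grid=grid)

free = MotionStudy.analyse(image, truth)          # motion-free MBF
peak = wp.peak_frame(image.tac(truth.myocardium_mask))
traj = next(t for t in wp.build_catalogue(grid, peak)
            if t.label == "Stress Agent 1")       # 10 mm step, +y and +z
moved = wp.apply_motion(image, traj)
uncorr = MotionStudy.analyse(moved, truth)
dev = DeviationReport.from_results(uncorr, free)

corrected = wp.correct(moved, wp.oracle_correction(traj))
post = MotionStudy.analyse(corrected, truth)
```

which prints (values in mL·min⁻¹·g⁻¹):

```
motion-free: {'LAD': 2.42, 'RCA': 2.29, 'LCx': 2.34} global 2.36
uncorrected: {'LAD': 3.06, 'RCA': 1.05, 'LCx': 2.63}
deviation %: {'LAD': 26.5, 'RCA': -54.1, 'LCx': 12.7, 'global': -1.4} large artifact: True
corrected:   {'LAD': 2.41, 'RCA': 2.29, 'LCx': 2.34}
```

The anterior+cranial step drags low-activity lung into the anterior (LAD)
region — apparent washout speeds up and MBF is overestimated by 26% —
while the inferior (RCA) region samples slow sub-diaphragmatic tissue and
MBF collapses by 54%: the classic anterior-hyperperfusion /
inferior-defect motion artifact, while global MBF barely moves. Undoing
the known motion restores every territory to within interpolation error
of the motion-free values.

A single time-activity curve can also be fitted statsmodels-style:

```python
model = wp.OneTissueModel(tac, aif, grid)
result = model.fit()
print(result.summary())       # MBF, PTF, V_A with standard errors
```

The full study — a seeded 10-subject population × 16 motions × one or
more correction approaches, with deviation heatmaps, signed-rank tests,
residual-motion tables, interpretation-change counts and Bland–Altman
summaries — runs through `wp.run_study(wp.StudyDesign(...))` or the CLI:

```sh
waterpet simulate --seed 1 --out scan/
waterpet inject --image scan/dynamic.nii.gz --timing scan/frame_timing.txt \
                --motion "Linear Slide 2" --labels scan/labels.nii.gz --out moved.nii.gz
waterpet fit --image moved.nii.gz --timing scan/frame_timing.txt \
             --masks scan/labels.nii.gz --out results/
waterpet study run --design design.yaml --out study_out/
```

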