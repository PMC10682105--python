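"""Simulated patient motion: catalogue of 16 trajectories and injection.

Four families of inter-frame rigid translations are simulated, mirroring
typical patient motion during stress ¹⁵O-water PET:

* **StressAgent 1–4** — sustained step of 10 or 20 mm simultaneously in the
  anterior (+y) and cranial (+z) direction, starting 30 or 60 s into the
  scan (reaction to the stress agent).
* **LinearSlide 1–4** — 10 or 20 mm linear slide caudally (−z), either over
  the whole scan or from 1 min post-injection, reaching full amplitude at
  the final frame mid-time.
* **PeakCough 1–2 / LateCough 1–4** — 10 or 20 mm anterior (+y) displacement
  of a single frame: at the peak of the myocardial time-activity curve, or
  the frames containing t = 1 min and t = 2 min.
* **CardiacCreep 1–2** — 5 or 10 mm linear cranial (+z) slide from 1 min
  post-injection until the end of the scan.

Onset times for the step/slide variants are a documented reconstruction:
amplitudes, directions and timings follow the catalogue description, and
the exact amplitude-to-onset pairing is fixed here once.

Injection resamples each frame exactly once from the original frame
(quintic B-spline by default), so repeated edits never accumulate
interpolation error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage

from .frames import FrameTimeGrid
from .phantom import DynamicImage

__all__ = [
    "MotionTrajectory",
    "build_catalogue",
    "peak_frame",
    "apply_motion",
    "translate_frames",
]

Family = Literal["StressAgent", "LinearSlide", "PeakCough", "LateCough", "CardiacCreep"]

CATALOGUE_FAMILIES = ("StressAgent", "LinearSlide", "PeakCough", "LateCough", "CardiacCreep")

#: Catalogue amplitude bounds, mm.
AMPLITUDE_MIN, AMPLITUDE_MAX = 5.0, 20.0


@dataclass(frozen=True)
class MotionTrajectory:
    """Per-frame rigid translation (Δx, Δy, Δz) in mm.

    Positive components move the patient right→left (+x), posterior→anterior
    (+y) and caudal→cranial (+z).
    """

    label: str
    family: str
    shifts: np.ndarray            # (n_frames, 3) mm

    def __post_init__(self) -> None:
        shifts = np.asarray(self.shifts, dtype=float)
        object.__setattr__(self, "shifts", shifts)
        if shifts.ndim != 2 or shifts.shape[1] != 3:
            raise ValueError("shifts must be (n_frames, 3)")
        # the 5-20 mm amplitude bound is a property of the catalogue, not of
        # arbitrary user trajectories
        if self.family in CATALOGUE_FAMILIES:
            amp = np.abs(shifts).max() if shifts.size else 0.0
            if amp > 0 and not (AMPLITUDE_MIN <= amp <= AMPLITUDE_MAX):
                raise ValueError(
                    f"peak amplitude {amp:g} mm outside the catalogue range "
                    f"[{AMPLITUDE_MIN:g}, {AMPLITUDE_MAX:g}] mm"
                )

    def __len__(self) -> int:
        return self.shifts.shape[0]

    @property
    def max_amplitude(self) -> float:
        return float(np.abs(self.shifts).max())

    def negated(self) -> "MotionTrajectory":
        return MotionTrajectory(self.label + " (negated)", self.family, -self.shifts)

    @classmethod
    def zero(cls, n_frames: int, label: str = "none") -> "MotionTrajectory":
        return cls(label, "none", np.zeros((n_frames, 3)))


def peak_frame(tac: np.ndarray) -> int:
    """Frame index of the maximum of a time-activity curve (earliest on ties)."""
    tac = np.asarray(tac, dtype=float)
    if tac.size == 0:
        raise ValueError("empty time-activity curve")
    if not np.any(tac):
        raise ValueError("all-zero time-activity curve has no peak")
    return int(np.argmax(tac))


def _step(grid: FrameTimeGrid, onset_s: float, vec: np.ndarray) -> np.ndarray:
    """Full displacement ``vec`` for every frame with mid-time >= onset."""
    shifts = np.zeros((len(grid), 3))
    shifts[grid.mid_times >= onset_s] = vec
    return shifts


def _slide(grid: FrameTimeGrid, onset_s: float, vec: np.ndarray) -> np.ndarray:
    """Linear ramp from 0 at onset to ``vec`` at the final frame mid-time.

    Per-frame values are rounded to whole millimetres: the catalogue is
    specified at the 1-mm resolution of the correction workflow, so a
    ground-truth correction can negate it exactly.
    """
    mids = grid.mid_times
    frac = np.clip((mids - onset_s) / (mids[-1] - onset_s), 0.0, 1.0)
    return np.round(frac[:, None] * vec[None, :])


def _single(grid: FrameTimeGrid, frame: int, vec: np.ndarray) -> np.ndarray:
    shifts = np.zeros((len(grid), 3))
    shifts[frame] = vec
    return shifts


def build_catalogue(grid: FrameTimeGrid, peak_frame_index: int) -> list[MotionTrajectory]:
    """The 16-trajectory simulated-motion catalogue on a frame grid.

    ``peak_frame_index`` locates the myocardial TAC peak for the peak-cough
    entries (use :func:`peak_frame` on the phantom's myocardial curve).
    """
    if not 0 <= peak_frame_index < len(grid):
        raise ValueError("peak frame outside the grid")
    if grid.total_duration < 120.0 + grid.durations[-1] / 2:
        raise ValueError("grid shorter than 2 minutes: late-cough frames undefined")
    y, z = np.array([0.0, 1.0, 0.0]), np.array([0.0, 0.0, 1.0])
    cat: list[MotionTrajectory] = []

    # reaction to the stress agent: sustained anterior+cranial step
    for i, (amp, onset) in enumerate([(10, 30), (20, 30), (10, 60), (20, 60)], 1):
        cat.append(
            MotionTrajectory(f"Stress Agent {i}", "StressAgent", _step(grid, onset, amp * (y + z)))
        )
    # caudal linear slide, whole scan or from 1 min
    for i, (amp, onset) in enumerate([(10, 0), (20, 0), (10, 60), (20, 60)], 1):
        cat.append(
            MotionTrajectory(f"Linear Slide {i}", "LinearSlide", _slide(grid, onset, -amp * z))
        )
    # single-frame anterior coughs
    for i, amp in enumerate([10, 20], 1):
        cat.append(
            MotionTrajectory(f"Peak Cough {i}", "PeakCough", _single(grid, peak_frame_index, amp * y))
        )
    late_frames = [grid.frame_containing(60.0), grid.frame_containing(120.0)]
    i = 1
    for frame in late_frames:
        for amp in (10, 20):
            cat.append(
                MotionTrajectory(f"Late Cough {i}", "LateCough", _single(grid, frame, amp * y))
            )
            i += 1
    # cardiac creep: cranial linear slide from 1 min
    for i, amp in enumerate([5, 10], 1):
        cat.append(
            MotionTrajectory(f"Cardiac Creep {i}", "CardiacCreep", _slide(grid, 60, amp * z))
        )
    assert len(cat) == 16
    return cat


def translate_frames(image: DynamicImage, shifts_mm: np.ndarray, order: int = 5) -> DynamicImage:
    """Resample each frame once by its (Δx, Δy, Δz) translation in mm.

    ``order=5`` (default) is quintic B-spline (a near-ideal translation
    interpolator), ``order=1`` trilinear and ``order=0`` nearest neighbour; voxels shifted in from outside the field
    of view are zero.  Frames with zero shift are copied bit-identically.
    """
    shifts_mm = np.asarray(shifts_mm, dtype=float)
    if shifts_mm.shape != (image.n_frames, 3):
        raise ValueError("shifts must be (n_frames, 3) matching the image")
    margin_vox = np.min(image.spatial_shape) / 2
    if np.abs(shifts_mm).max() / image.voxel_size > margin_vox:
        import warnings

        warnings.warn("shift exceeds the grid margin; content will be truncated")
    out = np.empty_like(image.voxels)
    shifts_vox = shifts_mm / image.voxel_size
    for f in range(image.n_frames):
        if np.all(shifts_vox[f] == 0):
            out[f] = image.voxels[f]
        else:
            ndimage.shift(
                image.voxels[f], shifts_vox[f], output=out[f],
                order=order, mode="constant", cval=0.0, prefilter=order > 1,
            )
    return DynamicImage(out, image.voxel_size, image.frame_grid)


def apply_motion(
    image: DynamicImage,
    traj: MotionTrajectory,
    order: int = 5,
) -> DynamicImage:
    """Inject per-frame rigid translations into a dynamic image.

    Each frame is resampled exactly once from the input frame by its
    trajectory vector; see :func:`translate_frames` for resampling rules.
    """
    if len(traj) != image.n_frames:
        raise ValueError("trajectory length must equal the frame count")
    return translate_frames(image, traj.shifts, order=order)
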