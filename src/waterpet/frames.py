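"""Dynamic frame timing.

A dynamic PET acquisition is binned into contiguous time frames of varying
duration; every curve in this package (arterial input, tissue activity) is a
vector of frame *averages* on one of these grids, never point samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = ["FrameTimeGrid", "build_frame_grid", "DEFAULT_FRAME_STRUCTURE"]

#: Clinical 4-minute dynamic structure: 10x5 s, 4x10 s, 2x15 s, 3x20 s, 2x30 s.
DEFAULT_FRAME_STRUCTURE: tuple[tuple[int, float], ...] = (
    (10, 5.0),
    (4, 10.0),
    (2, 15.0),
    (3, 20.0),
    (2, 30.0),
)


@dataclass(frozen=True)
class FrameTimeGrid:
    """Start/end times (seconds) of each dynamic frame.

    Frames are contiguous (``end[i] == start[i+1]``), strictly increasing and
    start at t = 0.
    """

    frame_starts: np.ndarray
    frame_ends: np.ndarray

    def __post_init__(self) -> None:
        starts = np.asarray(self.frame_starts, dtype=float)
        ends = np.asarray(self.frame_ends, dtype=float)
        object.__setattr__(self, "frame_starts", starts)
        object.__setattr__(self, "frame_ends", ends)
        if starts.ndim != 1 or starts.shape != ends.shape or starts.size == 0:
            raise ValueError("frame_starts/frame_ends must be equal-length 1-D arrays")
        if starts[0] != 0.0:
            raise ValueError("frame grid must start at t = 0")
        if np.any(ends <= starts):
            raise ValueError("every frame must have positive duration")
        if starts.size > 1 and not np.allclose(ends[:-1], starts[1:]):
            raise ValueError("frames must be contiguous (end[i] == start[i+1])")

    def __len__(self) -> int:
        return int(self.frame_starts.size)

    @property
    def n_frames(self) -> int:
        return len(self)

    @property
    def durations(self) -> np.ndarray:
        """Frame durations in seconds."""
        return self.frame_ends - self.frame_starts

    @property
    def mid_times(self) -> np.ndarray:
        """Frame mid-times (start + end)/2 in seconds."""
        return 0.5 * (self.frame_starts + self.frame_ends)

    @property
    def total_duration(self) -> float:
        """Scan length in seconds."""
        return float(self.frame_ends[-1])

    def frame_containing(self, t: float) -> int:
        """Index of the frame whose interval [start, end) contains time ``t``."""
        if t < 0 or t >= self.total_duration:
            raise ValueError(f"time {t} s outside scan [0, {self.total_duration}) s")
        return int(np.searchsorted(self.frame_starts, t, side="right") - 1)

    def to_file(self, path: str | Path) -> None:
        """Write a two-column plain-text timing file (start end, seconds)."""
        with open(path, "w") as fh:
            fh.write("# frame_start_s frame_end_s\n")
            for s, e in zip(self.frame_starts, self.frame_ends):
                fh.write(f"{s:g} {e:g}\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "FrameTimeGrid":
        """Read a two-column timing file (``#`` comments allowed)."""
        data = np.loadtxt(path, comments="#", ndmin=2)
        if data.shape[1] < 2:
            raise ValueError("timing file needs two columns: start end (seconds)")
        return cls(frame_starts=data[:, 0], frame_ends=data[:, 1])


def build_frame_grid(
    structure: Iterable[Sequence[float]] = DEFAULT_FRAME_STRUCTURE,
) -> FrameTimeGrid:
    """Build a contiguous frame grid from ``(count, duration_s)`` blocks.

    The default structure gives the clinical 21-frame, 240-s acquisition.
    """
    structure = list(structure)
    if not structure:
        raise ValueError("frame structure must not be empty")
    durations: list[float] = []
    for count, dur in structure:
        count = int(count)
        if count < 1:
            raise ValueError("frame counts must be >= 1")
        if dur <= 0:
            raise ValueError("frame durations must be > 0")
        durations.extend([float(dur)] * count)
    ends = np.cumsum(durations)
    starts = np.concatenate([[0.0], ends[:-1]])
    return FrameTimeGrid(frame_starts=starts, frame_ends=ends)
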