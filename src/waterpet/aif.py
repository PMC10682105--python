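"""Arterial input function (AIF) models.

The tracer bolus in arterial blood is modelled as a gamma-variate first pass
plus an optional slowly washing-out recirculation tail — the standard
analytic stand-in when an image-derived input function is not available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .frames import FrameTimeGrid

__all__ = ["AIFModel", "sample_aif", "frame_average_curve", "FINE_DT"]

#: Fine time step (s) used whenever a continuous curve must be frame-averaged
#: or convolved; 5-s early frames under-sample the bolus otherwise.
FINE_DT = 0.5


@dataclass(frozen=True)
class AIFModel:
    """Gamma-variate arterial bolus.

    C_a(t) = A * ((t-t0)/(alpha*beta))^alpha * exp(alpha - (t-t0)/beta) for
    t > t0, 0 before t0.  The curve peaks at t0 + alpha*beta with value A.  A fraction
    ``recirculation_fraction`` of the peak is added as a recirculation plateau
    that rises with the first pass and decays slowly (time constant
    ``recirculation_tau`` s).

    Parameters
    ----------
    t0 : bolus arrival delay, s
    amplitude : peak first-pass activity A, Bq/mL
    alpha : gamma shape, dimensionless (> 0)
    beta : gamma scale, s (> 0)
    recirculation_fraction : plateau height as a fraction of A, in [0, 1)
    recirculation_tau : washout time constant of the tail, s
    """

    t0: float = 10.0
    amplitude: float = 60_000.0
    alpha: float = 2.5
    beta: float = 4.8          # peak 12 s after arrival, FWHM ~ 18 s
    recirculation_fraction: float = 0.15
    recirculation_tau: float = 300.0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if not 0 <= self.recirculation_fraction < 1:
            raise ValueError("recirculation_fraction must be in [0, 1)")
        if self.amplitude < 0 or self.t0 < 0 or self.recirculation_tau <= 0:
            raise ValueError("amplitude, t0 must be >= 0 and recirculation_tau > 0")

    def __call__(self, times: np.ndarray) -> np.ndarray:
        return sample_aif(self, times)


def sample_aif(aif: AIFModel, times: np.ndarray) -> np.ndarray:
    """Evaluate the AIF at the given times (s). Zero before bolus arrival."""
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    tau = t - aif.t0
    curve = np.zeros_like(t)
    pos = tau > 0
    x = tau[pos] / aif.beta
    curve[pos] = aif.amplitude * (x / aif.alpha) ** aif.alpha * np.exp(aif.alpha - x)
    if aif.recirculation_fraction > 0:
        # tail rises with the first-pass cumulative and then decays slowly
        rise = 1.0 - np.exp(-tau[pos] / (aif.alpha * aif.beta))
        decay = np.exp(-np.maximum(tau[pos] - aif.alpha * aif.beta, 0.0) / aif.recirculation_tau)
        curve[pos] += aif.recirculation_fraction * aif.amplitude * rise * decay
    return curve


def frame_average_curve(values_fine: np.ndarray, t_fine: np.ndarray, grid: FrameTimeGrid) -> np.ndarray:
    """Average a finely sampled curve over each frame interval of ``grid``.

    ``t_fine`` must be uniformly spaced and cover the scan; trapezoidal
    integration over [start, end] divided by the frame duration.
    """
    out = np.empty(len(grid))
    for i, (s, e) in enumerate(zip(grid.frame_starts, grid.frame_ends)):
        sel = (t_fine >= s) & (t_fine <= e)
        ts, vs = t_fine[sel], values_fine[sel]
        if ts.size < 2:
            raise ValueError("fine grid too coarse for frame averaging")
        out[i] = np.trapezoid(vs, ts) / (ts[-1] - ts[0])
    return out


def fine_time_base(grid: FrameTimeGrid, dt: float = FINE_DT) -> np.ndarray:
    """Uniform fine time base spanning the scan, including both endpoints."""
    n = int(round(grid.total_duration / dt))
    return np.linspace(0.0, grid.total_duration, n + 1)
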