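"""Small shared DSP helpers: rectification, moving-average smoothing, metrics."""

from __future__ import annotations

import numpy as np

from .errors import ParameterError

__all__ = ["moving_average", "rectify_smooth", "signal_metric"]


def moving_average(x: np.ndarray, window_samples: int) -> np.ndarray:
    """Centered moving average with edge-value padding (no boundary taper);
    window <= 1 returns the input unchanged."""
    x = np.asarray(x, dtype=float)
    w = int(window_samples)
    if w <= 1:
        return x
    if x.size == 0:
        return x
    pad = w // 2
    xp = np.pad(x, (pad, w - 1 - pad), mode="edge")
    kernel = np.full(w, 1.0 / w)
    return np.convolve(xp, kernel, mode="valid")


def rectify_smooth(
    x: np.ndarray,
    sampling_rate: float,
    rectify: bool = True,
    smoothing_ms: float = 0.0,
) -> np.ndarray:
    """Full-wave rectify and moving-average smooth a trace segment.

    This is the conditioning chain applied before amplitude metrics
    (the classic "rectified and integrated" EMG treatment, with the
    integrator realized as a moving average).
    """
    y = np.abs(x) if rectify else np.asarray(x, dtype=float)
    if smoothing_ms > 0:
        y = moving_average(y, int(round(smoothing_ms * sampling_rate / 1000.0)))
    return y


def signal_metric(x: np.ndarray, metric: str = "rms") -> float:
    """Scalar amplitude metric of a (conditioned) segment.

    ``rms``            root-mean-square
    ``mean-rectified`` mean of the absolute value
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ParameterError("empty segment")
    if metric == "rms":
        return float(np.sqrt(np.mean(x**2)))
    if metric == "mean-rectified":
        return float(np.mean(np.abs(x)))
    raise ParameterError(f"unknown metric {metric!r}")
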