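"""Percent-of-background quantification of 5 Hz stimulation trains.

During a 5 Hz train the evoked responses fuse into a sustained elevation
of EMG / pressure activity.  The effect is quantified per channel as the
amplitude metric of the stimulation interval expressed as a percentage of
the same metric over the pre-stimulation "background" (BG) interval:
``%BG = 100 x stim_metric / bg_metric``.  The default metric is the RMS
of the rectified, 50 ms moving-average-smoothed signal; a mean-rectified
alternative is available and the choice is carried in the result.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .errors import (
    DegenerateBackgroundError,
    InvalidIntervalError,
)
from .signal import rectify_smooth, signal_metric

__all__ = [
    "BurstResult",
    "percent_of_background",
    "analyze_burst_session",
    "load_cohort_percentages",
]


@dataclass(frozen=True)
class BurstResult:
    """One %BG measurement: ``percent = 100 * stim_metric / bg_metric``."""

    animal: str
    group: str
    channel: str
    bg_metric: float
    stim_metric: float
    percent: float
    metric: str = "rms"
    site_id: str = ""


def percent_of_background(
    trace: np.ndarray,
    sampling_rate: float,
    stim_interval: tuple[float, float],
    bg_interval: tuple[float, float],
    *,
    metric: str = "rms",
    rectify: bool = True,
    smoothing_ms: float = 50.0,
    animal: str = "",
    group: str = "",
    channel: str = "",
    site_id: str = "",
) -> BurstResult:
    """Compute %BG for one channel; intervals are (start_s, stop_s).

    The background interval must precede and not overlap the stimulation
    interval; both must be non-empty and lie within the trace.  The
    metric is computed identically on both intervals after optional
    rectification and smoothing (applied per interval, so one interval
    never bleeds into the other through the smoother).
    """
    fs = float(sampling_rate)
    n = len(trace)
    for name, (a, b) in (("bg", bg_interval), ("stim", stim_interval)):
        if not (0 <= a < b <= n / fs):
            raise InvalidIntervalError(
                f"{name} interval ({a}, {b}) is empty, reversed or out of range"
            )
    if bg_interval[1] > stim_interval[0]:
        raise InvalidIntervalError("background must precede stimulation")

    def seg_metric(interval):
        a = int(round(interval[0] * fs))
        b = int(round(interval[1] * fs))
        seg = rectify_smooth(np.asarray(trace, dtype=float)[a:b], fs,
                             rectify=rectify, smoothing_ms=smoothing_ms)
        return signal_metric(seg, metric)

    bg_m = seg_metric(bg_interval)
    stim_m = seg_metric(stim_interval)
    if bg_m == 0:
        raise DegenerateBackgroundError("background metric is zero")
    return BurstResult(
        animal=animal, group=group, channel=channel,
        bg_metric=bg_m, stim_metric=stim_m,
        percent=100.0 * stim_m / bg_m, metric=metric, site_id=site_id,
    )


def _blank_artifacts(trace: np.ndarray, event_indices: np.ndarray,
                     blank_samples: int) -> np.ndarray:
    """Interpolate across the stimulus-artifact samples after each pulse."""
    out = np.asarray(trace, dtype=float).copy()
    n = out.size
    for i in event_indices:
        a = max(int(i) - 1, 0)
        b = min(int(i) + blank_samples, n - 1)
        out[a + 1 : b] = np.interp(np.arange(a + 1, b), [a, b],
                                   [out[a], out[b]])
    return out


def analyze_burst_session(
    session,
    *,
    metric: str = "rms",
    rectify: bool = True,
    smoothing_ms: float = 50.0,
    bg_window_s: float | None = None,
    artifact_blank_ms: float = 2.0,
) -> pd.DataFrame:
    """%BG for every (site, channel) of a burst-mode session.

    The stimulation interval per site runs from its first pulse to one
    inter-pulse period past its last pulse; the background interval is
    the ``bg_window_s`` (default: everything available in the block)
    immediately preceding train onset.  Stimulus-artifact samples
    (``artifact_blank_ms`` after each pulse) are interpolated away before
    the metric is computed, so artifacts do not masquerade as evoked
    activity.
    """
    fs = session.sampling_rate
    period = 1.0 / session.protocol.frequency_hz
    rows = []
    groups = session.site_groups()
    animal = session.metadata.get("animal_id", "")
    blank_n = int(round(artifact_blank_ms * fs / 1000.0))
    event_idx = np.round(session.events["time_s"].to_numpy() * fs).astype(int)
    channels = {
        name: _blank_artifacts(trace, event_idx, blank_n) if blank_n > 0 else trace
        for name, trace in session.channels.items()
    }
    for block in session.metadata["site_blocks"]:
        site = block["site_id"]
        ev = session.events[session.events["site_id"] == site]
        t0 = float(ev["time_s"].min())
        t1 = float(ev["time_s"].max()) + period
        bg_start = block["start_s"]
        if bg_window_s is not None:
            bg_start = max(bg_start, t0 - bg_window_s)
        for ch, trace in channels.items():
            r = percent_of_background(
                trace, fs, (t0, t1), (bg_start, t0),
                metric=metric, rectify=rectify, smoothing_ms=smoothing_ms,
                animal=animal, group=groups.get(site, ""), channel=ch,
                site_id=site,
            )
            rows.append((r.animal, r.group, r.channel, r.site_id,
                         r.bg_metric, r.stim_metric, r.percent))
    return pd.DataFrame(rows, columns=["animal", "group", "channel", "site_id",
                                       "bg_metric", "stim_metric", "percent"])


def load_cohort_percentages() -> pd.DataFrame:
    """Reported per-animal %BG values for the five-cat cohort.

    Columns ``animal, channel, rostral_pct, caudal_pct``: the published
    percent-of-background responses of CYST, Detr and EUS to 5 Hz
    stimulation of the rostral vs caudal spinal region, one row per
    animal and channel.  These are the inputs of the paired Wilcoxon
    site-specificity tests.
    """
    with resources.files("eesmap.data").joinpath(
        "cat_cohort_burst_percent.csv"
    ).open() as fh:
        return pd.read_csv(fh)
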