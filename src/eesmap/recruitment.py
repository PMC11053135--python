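"""Recruitment curves, regression slopes, normalization and segment maps.

A recruitment curve plots evoked-response amplitude against stimulation
current for one (site, channel).  Its steepness summarizes how
effectively that spinal site recruits that output: the ordinary
least-squares slope is fitted over the rising limb only — from the lowest
current through the *first* current at which the maximum amplitude is
attained — so saturation and post-maximum decline do not dilute the
estimate.  Per animal and channel, slopes are normalized to the best site
(max = 100%) and the per-animal matrices are averaged across animals into
a sites x channels "segment map" (mean +/- SE per cell), with sites
additionally pooled into rostral vs caudal groups for the paired
summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptySelectionError, ParameterError
from .stats import mean_se

__all__ = [
    "RecruitmentCurve",
    "SegmentMap",
    "build_recruitment_curve",
    "fit_slope",
    "normalize_slopes",
    "slope_table",
    "build_segment_map",
    "plot_segment_map",
]


@dataclass
class RecruitmentCurve:
    """Current -> amplitude points for one (site, channel), with the fitted
    rising-limb regression.  ``regression_range`` is the (first, last)
    index pair of the points used; slope/intercept are NaN when fewer
    than two points fall in the range (``defined`` False)."""

    site_id: str
    channel: str
    currents_ua: np.ndarray
    amplitudes: np.ndarray
    slope: float = float("nan")
    intercept: float = float("nan")
    regression_range: tuple[int, int] | None = None
    defined: bool = False


@dataclass
class SegmentMap:
    """Cross-animal summary of normalized recruitment slopes.

    ``mean``/``se``: sites x channels DataFrames of the cross-animal mean
    and SE of the normalized slope (%); ``per_animal``: the tidy
    per-animal table; ``group_summary``: rostral/caudal aggregation per
    (channel, group) with absolute and normalized values.
    """

    mean: pd.DataFrame
    se: pd.DataFrame
    per_animal: pd.DataFrame
    group_summary: pd.DataFrame
    group_rule: str = "max"
    degenerate_channels: list[tuple[str, str]] = field(default_factory=list)


def build_recruitment_curve(measurements, site_id: str = "", channel: str = ""
                            ) -> RecruitmentCurve:
    """Assemble a recruitment curve from evoked measurements.

    ``measurements`` is an iterable of (current_uA, p2p, present) triples
    or a DataFrame with those columns.  Absent responses contribute
    amplitude 0; repeats at one current are averaged; points are sorted
    by current.
    """
    if isinstance(measurements, pd.DataFrame):
        df = measurements[["current_uA", "p2p", "present"]].copy()
    else:
        df = pd.DataFrame(list(measurements),
                          columns=["current_uA", "p2p", "present"])
    if df.empty:
        raise EmptySelectionError("no measurements for this (site, channel)")
    df["amp"] = np.where(df["present"].astype(bool), df["p2p"], 0.0)
    agg = df.groupby("current_uA", sort=True)["amp"].mean()
    return RecruitmentCurve(
        site_id=site_id,
        channel=channel,
        currents_ua=agg.index.to_numpy(dtype=float),
        amplitudes=agg.to_numpy(dtype=float),
    )


def fit_slope(curve: RecruitmentCurve) -> RecruitmentCurve:
    """Fit the rising-limb OLS slope of amplitude on current.

    The regression range runs from the lowest current through the first
    attainment of the maximum amplitude; later points (plateau, decline)
    are excluded.  A constant curve gets slope 0 over the full range; a
    range with fewer than two points leaves the slope undefined (the
    curve is flagged and later excluded from normalization).
    """
    x, y = curve.currents_ua, curve.amplitudes
    if x.size < 2:
        raise ParameterError("need >= 2 points to fit a slope")
    if np.all(y == y[0]):
        curve.slope, curve.intercept = 0.0, float(y[0])
        curve.regression_range = (0, int(x.size - 1))
        curve.defined = True
        return curve
    imax = int(np.argmax(y))  # argmax returns the FIRST attainment
    if imax < 1:
        curve.slope = curve.intercept = float("nan")
        curve.regression_range = (0, imax)
        curve.defined = False
        return curve
    xr, yr = x[: imax + 1], y[: imax + 1]
    slope, intercept = np.polyfit(xr, yr, 1)
    curve.slope, curve.intercept = float(slope), float(intercept)
    curve.regression_range = (0, imax)
    curve.defined = True
    return curve


def normalize_slopes(slopes) -> tuple[np.ndarray, bool]:
    """Normalize one animal's per-site slopes for one channel to percent of
    the best site.  Negative slopes are clamped to 0 first; an all-zero
    vector returns zeros with the degenerate flag set."""
    s = np.asarray(slopes, dtype=float)
    finite = s[np.isfinite(s)]
    if finite.size == 0:
        raise ParameterError("need at least one finite slope")
    s = np.clip(s, 0.0, None)
    top = np.nanmax(s)
    if top == 0:
        return np.zeros_like(s), True
    return s / top * 100.0, False


def slope_table(evoked_table: pd.DataFrame, animal: str = "animal01"
                ) -> pd.DataFrame:
    """Per-(site, channel) fitted slopes from a tidy evoked table."""
    rows = []
    for (site, ch), grp in evoked_table.groupby(["site_id", "channel"]):
        curve = build_recruitment_curve(grp, site_id=site, channel=ch)
        if curve.currents_ua.size >= 2:
            curve = fit_slope(curve)
        rows.append((animal, site, ch, curve.slope, curve.defined))
    return pd.DataFrame(rows, columns=["animal", "site_id", "channel",
                                       "slope", "defined"])


def build_segment_map(
    per_animal_slopes: pd.DataFrame,
    site_groups: dict[str, str],
    group_rule: str = "max",
) -> SegmentMap:
    """Aggregate per-animal slopes into the cross-animal segment map.

    ``per_animal_slopes`` needs columns ``animal, site_id, channel,
    slope`` (optionally ``defined``); ``site_groups`` maps site labels to
    "rostral"/"caudal".  Normalization is per (animal, channel) across
    sites; the group score per animal is the ``group_rule`` ("max" or
    "mean") over that animal's sites in the group, applied to both the
    absolute slope and its normalized value.
    """
    if group_rule not in ("max", "mean"):
        raise ParameterError(f"unknown group_rule {group_rule!r}")
    df = per_animal_slopes.copy()
    if df.empty:
        raise EmptySelectionError("no animals in the slope table")
    if "defined" in df.columns:
        df = df[df["defined"].astype(bool)]
    if df.empty:
        raise EmptySelectionError("no defined slopes to normalize")

    degenerate: list[tuple[str, str]] = []
    parts = []
    for (animal, ch), grp in df.groupby(["animal", "channel"]):
        norm, degen = normalize_slopes(grp["slope"].to_numpy())
        if degen:
            degenerate.append((animal, ch))
        g = grp.copy()
        g["norm_pct"] = norm
        parts.append(g)
    tidy = pd.concat(parts, ignore_index=True)

    mean = tidy.pivot_table(index="site_id", columns="channel",
                            values="norm_pct", aggfunc="mean")
    n_animals = tidy["animal"].nunique()
    se = tidy.pivot_table(
        index="site_id", columns="channel", values="norm_pct",
        aggfunc=lambda v: mean_se(v).se,
    )

    tidy["group"] = tidy["site_id"].map(site_groups)
    if tidy["group"].isna().any():
        missing = sorted(tidy.loc[tidy["group"].isna(), "site_id"].unique())
        raise ParameterError(f"sites without a rostral/caudal group: {missing}")
    agg = {"max": "max", "mean": "mean"}[group_rule]
    per_animal_group = tidy.groupby(["animal", "channel", "group"]).agg(
        slope=("slope", agg), norm_pct=("norm_pct", agg)
    ).reset_index()
    rows = []
    for (ch, group), grp in per_animal_group.groupby(["channel", "group"]):
        s_abs = mean_se(grp["slope"].to_numpy())
        s_norm = mean_se(grp["norm_pct"].to_numpy())
        rows.append((ch, group, s_abs.mean, s_abs.se,
                     s_norm.mean, s_norm.se, s_abs.n))
    group_summary = pd.DataFrame(
        rows, columns=["channel", "group", "slope_mean", "slope_se",
                       "norm_mean", "norm_se", "n"],
    )
    return SegmentMap(
        mean=mean, se=se, per_animal=tidy, group_summary=group_summary,
        group_rule=group_rule, degenerate_channels=degenerate,
    )


def plot_segment_map(segment_map: SegmentMap, path=None, site_order=None):
    """Heatmap of the cross-animal mean normalized slopes (sites x channels)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    m = segment_map.mean
    if site_order is not None:
        m = m.reindex([s for s in site_order if s in m.index])
    fig, ax = plt.subplots(figsize=(1.2 + 1.1 * m.shape[1], 1.0 + 0.5 * m.shape[0]))
    im = ax.imshow(m.to_numpy(), cmap="viridis", vmin=0, vmax=100, aspect="auto")
    ax.set_xticks(range(m.shape[1]), m.columns)
    ax.set_yticks(range(m.shape[0]), m.index)
    ax.set_xlabel("channel")
    ax.set_ylabel("stimulation site")
    fig.colorbar(im, ax=ax, label="normalized slope (%)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
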