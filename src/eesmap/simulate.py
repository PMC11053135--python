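"""Synthetic stimulation-locked multichannel recordings with known ground truth.

The generator emulates an acute epidural-stimulation mapping experiment in
a decerebrated animal: a monopolar electrode on the dorsal spinal cord
delivers 1 Hz pulse trains over a stepped current ladder at several
rostro-caudal sites while detrusor (Detr) and external urethral sphincter
(EUS) EMG, hindlimb tibialis anterior (TA) EMG and intravesical pressure
(CYST) are recorded.  Each pulse evokes, per channel, a stereotyped
waveform — a slow biphasic 200-250 ms wave for the detrusor and pressure
channels, a fast multiphasic complex for the striated muscles — whose
amplitude grows linearly with current above a recruitment threshold up to
saturation, scaled by a site-specific gain multiplier (rostral sites
recruit Detr/CYST, caudal sites recruit EUS).  A 5 Hz "burst" mode drives
a sustained train preceded by a quiet background segment for
percent-of-background analysis.

Everything stochastic (latency jitter, background noise, tonic activity)
derives from one master seed through fixed per-site substreams, so
sessions are bit-reproducible and adding a site never perturbs the
others.  A :class:`GroundTruth` record accompanies every session and makes
parameter-recovery tests possible.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError, ProtocolError
from .signal import rectify_smooth, signal_metric

__all__ = [
    "StimulationProtocol",
    "ChannelModel",
    "SiteProfile",
    "RecordingSession",
    "SiteChannelTruth",
    "GroundTruth",
    "waveform_template",
    "template_first_peak_offset",
    "recruitment_gain",
    "generate_session",
    "generate_burst_session",
    "study_defaults",
    "cohort_site_profiles",
    "generate_cohort",
]

# substream counter scheme: site i -> spawn_key (i,);
# session-level streams (tonic activity, lead-in noise) -> (_SESSION_KEY,);
# animal a of a cohort -> (_ANIMAL_KEY + a,)
_SESSION_KEY = 1 << 20
_ANIMAL_KEY = (1 << 20) + 1024


@dataclass(frozen=True)
class StimulationProtocol:
    """Pulse-train protocol: a 1 Hz stepped current ladder by default.

    Defaults follow the mapping protocol: 1 Hz pulses, 10-800 uA in 10 uA
    increments, 10 pulses per amplitude, 0.3 ms pulse width.
    ``train_duration_s`` is only used by the 5 Hz burst mode.
    """

    frequency_hz: float = 1.0
    current_start_ua: float = 10.0
    current_stop_ua: float = 800.0
    current_step_ua: float = 10.0
    pulses_per_current: int = 10
    pulse_width_ms: float = 0.3
    train_duration_s: float | None = None

    def __post_init__(self) -> None:
        if self.frequency_hz <= 0:
            raise ParameterError("frequency must be > 0")
        if self.current_step_ua <= 0:
            raise ParameterError("current_step must be > 0")
        if self.current_start_ua > self.current_stop_ua:
            raise ParameterError("current_start must be <= current_stop")
        if self.pulses_per_current < 1:
            raise ParameterError("pulses_per_current must be >= 1")
        if self.pulse_width_ms <= 0:
            raise ParameterError("pulse_width must be > 0")

    def currents(self) -> np.ndarray:
        """The current ladder in uA, inclusive of the stop value."""
        return np.arange(
            self.current_start_ua,
            self.current_stop_ua + self.current_step_ua / 2.0,
            self.current_step_ua,
        )


@dataclass(frozen=True)
class ChannelModel:
    """Response model of one recorded channel.

    ``kind`` selects the evoked-waveform template: "slow" (biphasic
    200-250 ms wave, detrusor EMG), "fast" (short multiphasic complex,
    striated muscle EMG) or "pressure" (single slow positive wave).
    ``recruitment_gain`` is in amplitude units per uA above threshold;
    ``tonic_rms`` adds ongoing band-limited background activity (used by
    the burst mode), in the channel's amplitude units.
    """

    name: str
    kind: str
    latency_mean_ms: float
    template_duration_ms: float
    recruitment_threshold_ua: float
    recruitment_gain: float
    saturation_ua: float
    noise_sd: float
    latency_jitter_sd_ms: float = 0.5
    tonic_rms: float = 0.0
    unit: str = "mV"

    def __post_init__(self) -> None:
        if self.kind not in ("fast", "slow", "pressure"):
            raise ParameterError(f"unknown channel kind {self.kind!r}")
        if self.latency_mean_ms <= 0:
            raise ParameterError("latency_mean must be > 0")
        if self.template_duration_ms <= 0:
            raise ParameterError("template_duration must be > 0")
        if self.recruitment_gain < 0:
            raise ParameterError("recruitment_gain must be >= 0")
        if self.saturation_ua < self.recruitment_threshold_ua:
            raise ParameterError("saturation must be >= recruitment threshold")
        if self.noise_sd < 0 or self.tonic_rms < 0:
            raise ParameterError("noise_sd and tonic_rms must be >= 0")


@dataclass(frozen=True)
class SiteProfile:
    """One epidural stimulation site: label, rostral/caudal group and
    per-channel dimensionless gain multipliers.  ``latency_overrides``
    replaces a channel's mean latency at this site (e.g. the shorter EUS
    latency at caudal sites)."""

    site_id: str
    group: str
    multipliers: dict[str, float]
    latency_overrides: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in ("rostral", "caudal"):
            raise ParameterError("group must be 'rostral' or 'caudal'")
        if any(m < 0 for m in self.multipliers.values()):
            raise ParameterError("gain multipliers must be >= 0")


@dataclass
class RecordingSession:
    """Multichannel traces plus the stimulation-event table.

    ``events`` has columns ``time_s`` (absolute seconds from recording
    start), ``current_uA`` and ``site_id``, sorted by time.
    """

    sampling_rate: float
    channels: dict[str, np.ndarray]
    units: dict[str, str]
    events: pd.DataFrame
    protocol: StimulationProtocol
    metadata: dict

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def site_ids(self) -> list[str]:
        return [b["site_id"] for b in self.metadata.get("site_blocks", [])]

    def site_groups(self) -> dict[str, str]:
        return {b["site_id"]: b["group"] for b in self.metadata.get("site_blocks", [])}

    def validate(self) -> None:
        """Raise ParameterError if a container invariant is violated."""
        if self.sampling_rate <= 0:
            raise ParameterError("sampling_rate must be > 0")
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) != 1:
            raise ParameterError("all channel arrays must have equal length")
        t = self.events["time_s"].to_numpy()
        if t.size and (np.any(np.diff(t) <= 0)):
            raise ParameterError("event times must be strictly increasing")
        if t.size and (t[0] < 0 or t[-1] >= self.duration_s):
            raise ParameterError("event times must lie within the trace")


@dataclass(frozen=True)
class SiteChannelTruth:
    """True generator parameters for one (site, channel)."""

    site_id: str
    channel: str
    latency_ms: float
    threshold_ua: float
    gain_effective: float  # channel gain x site multiplier, units/uA
    pulse_amplitudes: np.ndarray  # true template p2p per pulse, event order


@dataclass
class GroundTruth:
    """All true parameters behind a generated session."""

    entries: dict[tuple[str, str], SiteChannelTruth]
    burst_intervals: dict[str, tuple[float, float, float, float]] = field(
        default_factory=dict
    )  # site -> (bg_start, bg_stop, stim_start, stim_stop), seconds
    expected_percent: dict[tuple[str, str], float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Templates and the recruitment law
# ---------------------------------------------------------------------------

def waveform_template(
    kind: str,
    duration_ms: float,
    amplitude: float,
    sampling_rate: float,
) -> np.ndarray:
    """A zero-baseline evoked-response template with the given peak-to-peak.

    ``fast``     three alternating Gaussian lobes (multiphasic, EMG-like;
                 lobe amplitudes +1, -1.3, +0.3 so the template integrates
                 to ~0, as AC-coupled EMG does)
    ``slow``     a short positive raised-cosine lobe followed by a longer,
                 shallower negative one (biphasic slow wave; lobe areas
                 match so the template integrates to ~0)
    ``pressure`` a single positive lobe with a fast half-cosine rise and a
                 slow half-cosine decay (pressure transients are unipolar;
                 no zero-integral constraint)

    Rise times are short relative to the waveform so that the first peak
    sits early in the template and responses remain causal (onset after
    the stimulus) at the configured latencies.

    The returned array's max-minus-min equals ``amplitude`` to within
    floating-point rounding.
    """
    if duration_ms <= 0:
        raise ParameterError("duration must be > 0")
    if sampling_rate <= 0:
        raise ParameterError("sampling_rate must be > 0")
    if amplitude < 0:
        raise ParameterError("amplitude must be >= 0")
    n = int(round(duration_ms * sampling_rate / 1000.0))
    if n < 4:
        raise ParameterError("template too short for the sampling rate")
    if amplitude == 0:
        return np.zeros(n)

    if kind == "fast":
        t = (np.arange(n) + 0.5) / n
        sd = 1.0 / 12.0
        y = np.zeros(n)
        for center, amp in ((0.25, 1.0), (0.50, -1.3), (0.75, 0.3)):
            y += amp * np.exp(-0.5 * ((t - center) / sd) ** 2)
    elif kind == "slow":
        split = max(2, int(round(0.3 * n)))  # first (positive) lobe: 30%
        y = np.zeros(n)
        y[:split] = np.hanning(split)
        # negative lobe amplitude chosen so the lobe areas cancel
        y[split:] = -np.hanning(n - split) * (split / (n - split))
    elif kind == "pressure":
        rise = max(2, int(round(0.15 * n)))  # fast rise, slow decay
        y = np.zeros(n)
        y[:rise] = 0.5 - 0.5 * np.cos(np.pi * np.arange(rise) / rise)
        y[rise:] = 0.5 + 0.5 * np.cos(np.pi * np.arange(n - rise) / (n - rise))
    else:
        raise ParameterError(f"unknown template kind {kind!r}")
    return y * (amplitude / (y.max() - y.min()))


def template_first_peak_offset(template: np.ndarray) -> int:
    """Sample index of the template's first local extremum (its first peak)."""
    y = template
    for i in range(1, len(y) - 1):
        if y[i] == 0:
            continue
        if (y[i] - y[i - 1]) * (y[i + 1] - y[i]) <= 0:
            return i
    return int(np.argmax(np.abs(y)))


def recruitment_gain(
    current: float,
    threshold: float,
    gain: float,
    saturation: float,
) -> float:
    """Piecewise-linear recruitment law mapping current (uA) to response
    amplitude: zero below threshold, linear with slope ``gain`` up to
    saturation, constant beyond."""
    if saturation < threshold:
        raise ParameterError("saturation must be >= threshold")
    if current < 0:
        raise ParameterError("current must be >= 0")
    effective = min(current, saturation)
    return gain * max(0.0, effective - threshold)


# ---------------------------------------------------------------------------
# Session synthesis
# ---------------------------------------------------------------------------

def _site_rng(seed: int, site_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(site_index,)))


def _session_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_SESSION_KEY,)))


def _tonic_activity(rng: np.random.Generator, n: int, rms: float,
                    sampling_rate: float) -> np.ndarray:
    """Band-limited stationary background activity with the requested RMS."""
    raw = rng.standard_normal(n)
    w = max(1, int(round(0.005 * sampling_rate)))  # ~5 ms correlation
    kernel = np.full(w, 1.0 / w)
    y = np.convolve(raw, kernel, mode="same")
    r = np.sqrt(np.mean(y**2))
    return y * (rms / r) if r > 0 else y


def _check_unique(items: list[str], what: str) -> None:
    if len(set(items)) != len(items):
        raise ParameterError(f"duplicate {what} labels")


def _base_templates(channel_models: list[ChannelModel], fs: float):
    templates = {}
    for ch in channel_models:
        base = waveform_template(ch.kind, ch.template_duration_ms, 1.0, fs)
        templates[ch.name] = (base, template_first_peak_offset(base))
    return templates


def _validate_setup(site_profiles, channel_models, inter_block_gap_s) -> None:
    if not site_profiles or not channel_models:
        raise ParameterError("need >= 1 site and >= 1 channel")
    _check_unique([s.site_id for s in site_profiles], "site")
    _check_unique([c.name for c in channel_models], "channel")
    if inter_block_gap_s < 0:
        raise ProtocolError("stimulation blocks overlap (negative inter-block gap)")
    for s in site_profiles:
        for c in channel_models:
            if c.name not in s.multipliers:
                raise ParameterError(
                    f"site {s.site_id} has no gain multiplier for channel {c.name}"
                )


def _add_artifacts(traces, event_indices, amplitude: float) -> None:
    """One-sample full-scale deflection at each pulse time, every channel."""
    for trace in traces.values():
        trace[event_indices] += amplitude


def _insert_site_responses(
    traces, site, channel_models, templates, event_indices, event_currents,
    rng, fs, truth_entries,
):
    """Add scaled, jittered templates for one site's events."""
    n_total = len(next(iter(traces.values())))
    for ch in channel_models:
        trace = traces[ch.name]
        base, peak_off = templates[ch.name]
        mult = site.multipliers[ch.name]
        lat_mean = site.latency_overrides.get(ch.name, ch.latency_mean_ms)
        jsd = ch.latency_jitter_sd_ms
        jitter = rng.normal(0.0, jsd, size=len(event_indices)) if jsd > 0 else (
            np.zeros(len(event_indices)))
        jitter = np.clip(jitter, -3.0 * jsd, 3.0 * jsd)
        amps = np.array([
            recruitment_gain(c, ch.recruitment_threshold_ua,
                             ch.recruitment_gain, ch.saturation_ua) * mult
            for c in event_currents
        ])
        for k, (e_idx, amp) in enumerate(zip(event_indices, amps)):
            if amp <= 0:
                continue
            shift = int(round((lat_mean + jitter[k]) * fs / 1000.0)) - peak_off
            start = e_idx + shift
            stop = start + base.size
            a = max(start, 0)
            b = min(stop, n_total)
            if a < b:
                trace[a:b] += amp * base[a - start : b - start]
        truth_entries[(site.site_id, ch.name)] = SiteChannelTruth(
            site_id=site.site_id,
            channel=ch.name,
            latency_ms=lat_mean,
            threshold_ua=ch.recruitment_threshold_ua,
            gain_effective=ch.recruitment_gain * mult,
            pulse_amplitudes=amps,
        )


def generate_session(
    protocol: StimulationProtocol,
    site_profiles: list[SiteProfile],
    channel_models: list[ChannelModel],
    seed: int,
    *,
    sampling_rate: float = 20000.0,
    lead_in_s: float = 1.0,
    inter_block_gap_s: float = 1.0,
    artifact_amplitude: float = 25.0,
    animal_id: str = "animal01",
) -> tuple[RecordingSession, GroundTruth]:
    """Synthesize a 1 Hz current-ladder mapping session.

    For each site, a contiguous block delivers the full ladder
    (``pulses_per_current`` pulses per rung at ``frequency_hz``).  Each
    pulse adds, per channel, the channel template scaled by the
    recruitment law times the site multiplier, with its first peak placed
    ``latency + jitter`` after the pulse; a one-sample stimulus artifact
    marks the pulse time, and white Gaussian noise covers the whole trace.
    Identical arguments and seed yield a bit-identical session.
    """
    _validate_setup(site_profiles, channel_models, inter_block_gap_s)
    if sampling_rate <= 0:
        raise ParameterError("sampling_rate must be > 0")
    fs = float(sampling_rate)
    currents = protocol.currents()
    period = 1.0 / protocol.frequency_hz
    pulses_per_site = currents.size * protocol.pulses_per_current
    block_s = pulses_per_site * period
    n_sites = len(site_profiles)
    total_s = lead_in_s + n_sites * (block_s + inter_block_gap_s)
    n_total = int(round(total_s * fs))

    traces = {c.name: np.zeros(n_total) for c in channel_models}
    templates = _base_templates(channel_models, fs)
    truth_entries: dict[tuple[str, str], SiteChannelTruth] = {}
    rows = []
    site_blocks = []

    # session-level streams first: tonic activity, then lead-in noise
    srng = _session_rng(seed)
    lead_n = int(round(lead_in_s * fs))
    for ch in channel_models:
        if ch.tonic_rms > 0:
            traces[ch.name] += _tonic_activity(srng, n_total, ch.tonic_rms, fs)
    noise_lead = {
        ch.name: srng.standard_normal(lead_n) * ch.noise_sd if ch.noise_sd > 0 else None
        for ch in channel_models
    }

    for i, site in enumerate(site_profiles):
        start_s = lead_in_s + i * (block_s + inter_block_gap_s)
        pulse_times = start_s + np.arange(pulses_per_site) * period
        event_currents = np.repeat(currents, protocol.pulses_per_current)
        event_indices = np.round(pulse_times * fs).astype(int)
        rng = _site_rng(seed, i)
        _insert_site_responses(
            traces, site, channel_models, templates, event_indices,
            event_currents, rng, fs, truth_entries,
        )
        _add_artifacts(traces, event_indices, artifact_amplitude)
        # per-site noise covers the block plus its trailing gap
        seg_a = int(round(start_s * fs))
        seg_b = int(round((start_s + block_s + inter_block_gap_s) * fs))
        seg_b = min(seg_b, n_total)
        for ch in channel_models:
            if ch.noise_sd > 0:
                traces[ch.name][seg_a:seg_b] += (
                    rng.standard_normal(seg_b - seg_a) * ch.noise_sd
                )
        for t, c in zip(pulse_times, event_currents):
            rows.append((t, float(c), site.site_id))
        site_blocks.append({
            "site_id": site.site_id, "group": site.group,
            "start_s": start_s, "stop_s": start_s + block_s,
        })

    for ch in channel_models:
        if noise_lead[ch.name] is not None:
            traces[ch.name][:lead_n] += noise_lead[ch.name]

    events = pd.DataFrame(rows, columns=["time_s", "current_uA", "site_id"])
    session = RecordingSession(
        sampling_rate=fs,
        channels=traces,
        units={c.name: c.unit for c in channel_models},
        events=events,
        protocol=protocol,
        metadata={
            "animal_id": animal_id,
            "seed": int(seed),
            "mode": "ladder",
            "lead_in_s": lead_in_s,
            "inter_block_gap_s": inter_block_gap_s,
            "artifact_amplitude": artifact_amplitude,
            "site_blocks": site_blocks,
        },
    )
    session.validate()
    return session, GroundTruth(entries=truth_entries)


def generate_burst_session(
    protocol: StimulationProtocol,
    site_profiles: list[SiteProfile],
    channel_models: list[ChannelModel],
    seed: int,
    *,
    sampling_rate: float = 20000.0,
    background_s: float = 5.0,
    inter_block_gap_s: float = 1.0,
    artifact_amplitude: float = 25.0,
    animal_id: str = "animal01",
) -> tuple[RecordingSession, GroundTruth]:
    """Synthesize a 5 Hz burst session for percent-of-background analysis.

    Per site: a noise/tonic-only background segment of ``background_s``
    seconds, then a pulse train at ``protocol.frequency_hz`` lasting
    ``protocol.train_duration_s`` at the ladder's top current.  The
    ground truth records the burst intervals and, per (site, channel),
    the percent-of-background expected from the pre-noise signal under
    the default RMS metric (rectified, 50 ms smoothed).
    """
    _validate_setup(site_profiles, channel_models, inter_block_gap_s)
    if sampling_rate <= 0:
        raise ParameterError("sampling_rate must be > 0")
    if protocol.train_duration_s is None or protocol.train_duration_s <= 0:
        raise ProtocolError("burst mode requires a positive train_duration_s")
    if background_s <= 0:
        raise ParameterError("background_s must be > 0")
    fs = float(sampling_rate)
    period = 1.0 / protocol.frequency_hz
    n_pulses = int(round(protocol.train_duration_s * protocol.frequency_hz))
    if n_pulses < 1:
        raise ProtocolError("train too short for one pulse")
    current = float(protocol.current_stop_ua)
    block_s = background_s + protocol.train_duration_s
    n_sites = len(site_profiles)
    total_s = n_sites * (block_s + inter_block_gap_s)
    n_total = int(round(total_s * fs))

    traces = {c.name: np.zeros(n_total) for c in channel_models}
    templates = _base_templates(channel_models, fs)
    truth = GroundTruth(entries={})
    rows = []
    site_blocks = []

    srng = _session_rng(seed)
    for ch in channel_models:
        if ch.tonic_rms > 0:
            traces[ch.name] += _tonic_activity(srng, n_total, ch.tonic_rms, fs)

    # deterministic + tonic signal, before measurement noise: the basis of
    # the ground-truth expected percent-of-background
    for i, site in enumerate(site_profiles):
        block_start = i * (block_s + inter_block_gap_s)
        train_start = block_start + background_s
        pulse_times = train_start + np.arange(n_pulses) * period
        event_indices = np.round(pulse_times * fs).astype(int)
        event_currents = np.full(n_pulses, current)
        rng = _site_rng(seed, i)
        _insert_site_responses(
            traces, site, channel_models, templates, event_indices,
            event_currents, rng, fs, truth.entries,
        )
        bg = (block_start, train_start)
        stim = (train_start, train_start + protocol.train_duration_s)
        truth.burst_intervals[site.site_id] = (bg[0], bg[1], stim[0], stim[1])
        for ch in channel_models:
            pre = traces[ch.name]
            bg_seg = rectify_smooth(pre[int(bg[0] * fs):int(bg[1] * fs)], fs,
                                    rectify=True, smoothing_ms=50.0)
            st_seg = rectify_smooth(pre[int(stim[0] * fs):int(stim[1] * fs)], fs,
                                    rectify=True, smoothing_ms=50.0)
            bg_m = signal_metric(bg_seg, "rms")
            st_m = signal_metric(st_seg, "rms")
            truth.expected_percent[(site.site_id, ch.name)] = (
                100.0 * st_m / bg_m if bg_m > 0 else float("nan")
            )
        # artifacts go in after the expected percent is computed: the burst
        # analysis blanks them, so the ground truth must exclude them too
        _add_artifacts(traces, event_indices, artifact_amplitude)
        for t in pulse_times:
            rows.append((t, current, site.site_id))
        site_blocks.append({
            "site_id": site.site_id, "group": site.group,
            "start_s": block_start, "stop_s": stim[1],
        })
        # measurement noise for this site's whole segment
        seg_a = int(round(block_start * fs))
        seg_b = min(int(round((block_start + block_s + inter_block_gap_s) * fs)),
                    n_total)
        for ch in channel_models:
            if ch.noise_sd > 0:
                traces[ch.name][seg_a:seg_b] += (
                    rng.standard_normal(seg_b - seg_a) * ch.noise_sd
                )

    events = pd.DataFrame(rows, columns=["time_s", "current_uA", "site_id"])
    session = RecordingSession(
        sampling_rate=fs,
        channels=traces,
        units={c.name: c.unit for c in channel_models},
        events=events,
        protocol=protocol,
        metadata={
            "animal_id": animal_id,
            "seed": int(seed),
            "mode": "burst",
            "background_s": background_s,
            "inter_block_gap_s": inter_block_gap_s,
            "artifact_amplitude": artifact_amplitude,
            "site_blocks": site_blocks,
        },
    )
    session.validate()
    return session, truth


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def study_defaults(
    *,
    current_stop_ua: float = 800.0,
    pulses_per_current: int = 10,
    noise_scale: float = 1.0,
) -> tuple[StimulationProtocol, list[SiteProfile], list[ChannelModel]]:
    """Default study conditions for the decerebrated-cat mapping setup.

    Channel mean latencies follow the reported group means (Detr 38.0 ms
    at both levels; EUS 13.7 ms rostral / 7.4 ms caudal; TA 14.6 / 9.0 ms),
    Detr/CYST gains are rostral-dominant and EUS gains caudal-dominant.
    Recruitment thresholds are 0 uA so that the fitted recruitment-curve
    slope equals the effective gain exactly on noise-free data; noise
    levels are phenomenological (none are reported for the original
    recordings) and scale with ``noise_scale``.
    """
    protocol = StimulationProtocol(
        frequency_hz=1.0,
        current_start_ua=10.0,
        current_stop_ua=current_stop_ua,
        current_step_ua=10.0,
        pulses_per_current=pulses_per_current,
        pulse_width_ms=0.3,
    )
    ns = noise_scale
    channels = [
        ChannelModel("Detr", "slow", 38.0, 225.0, 0.0, 0.004, 600.0,
                     0.05 * ns, latency_jitter_sd_ms=0.5, unit="mV"),
        ChannelModel("EUS", "fast", 13.7, 20.0, 0.0, 0.006, 600.0,
                     0.05 * ns, latency_jitter_sd_ms=0.3, unit="mV"),
        ChannelModel("TA", "fast", 14.6, 20.0, 0.0, 0.006, 600.0,
                     0.05 * ns, latency_jitter_sd_ms=0.3, unit="mV"),
        ChannelModel("CYST", "pressure", 38.0, 225.0, 0.0, 0.003, 600.0,
                     0.02 * ns, latency_jitter_sd_ms=1.0, unit="cmH2O"),
    ]
    caudal_lat = {"EUS": 7.4, "TA": 9.0}
    sites = [
        SiteProfile("T13", "rostral",
                    {"Detr": 1.00, "CYST": 1.00, "EUS": 0.30, "TA": 0.70}),
        SiteProfile("L1", "rostral",
                    {"Detr": 0.85, "CYST": 0.90, "EUS": 0.35, "TA": 0.80}),
        SiteProfile("L6", "caudal",
                    {"Detr": 0.30, "CYST": 0.25, "EUS": 0.70, "TA": 1.00},
                    latency_overrides=caudal_lat),
        SiteProfile("L7", "caudal",
                    {"Detr": 0.25, "CYST": 0.20, "EUS": 1.00, "TA": 0.90},
                    latency_overrides=caudal_lat),
        SiteProfile("S1", "caudal",
                    {"Detr": 0.20, "CYST": 0.15, "EUS": 0.90, "TA": 0.80},
                    latency_overrides=caudal_lat),
    ]
    return protocol, sites, channels


def cohort_site_profiles(
    base_sites: list[SiteProfile],
    n_animals: int,
    seed: int,
    variability: float = 0.2,
) -> list[list[SiteProfile]]:
    """Per-animal site profiles with lognormal gain variability.

    Each animal's multiplier for (site, channel) is the base multiplier
    times ``exp(N(0, variability))``, drawn from that animal's dedicated
    substream, emulating between-animal differences in electrode coupling
    and anatomy.
    """
    if n_animals < 1:
        raise ParameterError("need >= 1 animal")
    out = []
    for a in range(n_animals):
        rng = np.random.default_rng(
            np.random.SeedSequence(seed, spawn_key=(_ANIMAL_KEY + a,))
        )
        sites_a = []
        for s in base_sites:
            mult = {
                name: m * float(np.exp(rng.normal(0.0, variability)))
                for name, m in s.multipliers.items()
            }
            sites_a.append(SiteProfile(s.site_id, s.group, mult,
                                       copy.deepcopy(s.latency_overrides)))
        out.append(sites_a)
    return out


def generate_cohort(
    n_animals: int = 5,
    seed: int = 0,
    *,
    protocol: StimulationProtocol | None = None,
    base_sites: list[SiteProfile] | None = None,
    channel_models: list[ChannelModel] | None = None,
    variability: float = 0.2,
    sampling_rate: float = 20000.0,
    **session_kwargs,
) -> list[tuple[RecordingSession, GroundTruth]]:
    """A cohort of 1 Hz mapping sessions (default: the five-animal setup)."""
    if protocol is None or base_sites is None or channel_models is None:
        p0, s0, c0 = study_defaults()
        protocol = protocol or p0
        base_sites = base_sites or s0
        channel_models = channel_models or c0
    per_animal = cohort_site_profiles(base_sites, n_animals, seed, variability)
    out = []
    for a in range(n_animals):
        child = int(np.random.SeedSequence(seed, spawn_key=(a,)).generate_state(1)[0]
                    % 2**31)
        session, truth = generate_session(
            protocol, per_animal[a], channel_models, child,
            sampling_rate=sampling_rate,
            animal_id=f"animal{a + 1:02d}",
            **session_kwargs,
        )
        out.append((session, truth))
    return out
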