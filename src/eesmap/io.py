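"""Session container read/write.

A session lives in a directory:

* ``metadata.json`` — sampling rate, channel list with units, protocol,
  site blocks, seed and mode;
* one numeric file per channel, ``<name>.npy`` (default) or ``<name>.txt``
  (one sample per line);
* ``events.csv`` with header ``time_s,current_uA,site_id`` — absolute
  seconds from recording start;
* optionally ``ground_truth.json`` with the generator's true parameters.

``read_session`` validates the container invariants (equal channel
lengths, strictly increasing in-range event times, positive sampling
rate) and raises :class:`~eesmap.errors.FormatError` naming the offending
file, or :class:`~eesmap.errors.ValidationError` for invariant breaches.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError, ValidationError
from .simulate import (
    GroundTruth,
    RecordingSession,
    SiteChannelTruth,
    StimulationProtocol,
)

__all__ = ["write_session", "read_session", "write_ground_truth", "read_ground_truth"]


def write_session(
    session: RecordingSession,
    directory,
    *,
    truth: GroundTruth | None = None,
    fmt: str = "npy",
) -> Path:
    """Write a session (and optionally its ground truth) to a directory."""
    if fmt not in ("npy", "txt"):
        raise ParameterError(f"unknown channel file format {fmt!r}")
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    meta = {
        "sampling_rate": session.sampling_rate,
        "channels": [
            {"name": name, "unit": session.units.get(name, ""), "file": f"{name}.{fmt}"}
            for name in session.channels
        ],
        "protocol": dataclasses.asdict(session.protocol),
        "metadata": session.metadata,
    }
    (d / "metadata.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    for name, trace in session.channels.items():
        if fmt == "npy":
            np.save(d / f"{name}.npy", np.asarray(trace, dtype=np.float64))
        else:
            np.savetxt(d / f"{name}.txt", np.asarray(trace, dtype=np.float64),
                       fmt="%.10g")
    session.events.to_csv(d / "events.csv", index=False, float_format="%.8g")
    if truth is not None:
        write_ground_truth(truth, d / "ground_truth.json")
    return d


def read_session(directory) -> RecordingSession:
    """Load and validate a session container."""
    d = Path(directory)
    meta_path = d / "metadata.json"
    if not meta_path.exists():
        raise FormatError(f"missing file: {meta_path}")
    try:
        meta = json.loads(meta_path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"ill-formed file: {meta_path}: {exc}") from exc
    for key in ("sampling_rate", "channels", "protocol", "metadata"):
        if key not in meta:
            raise FormatError(f"ill-formed file: {meta_path}: missing key {key!r}")

    channels: dict[str, np.ndarray] = {}
    units: dict[str, str] = {}
    for ch in meta["channels"]:
        path = d / ch["file"]
        if not path.exists():
            raise FormatError(f"missing channel file: {path}")
        try:
            if path.suffix == ".npy":
                trace = np.load(path)
            else:
                trace = np.loadtxt(path, ndmin=1)
        except Exception as exc:  # numpy raises various things on truncation
            raise FormatError(f"ill-formed channel file: {path}: {exc}") from exc
        channels[ch["name"]] = np.asarray(trace, dtype=float)
        units[ch["name"]] = ch.get("unit", "")

    ev_path = d / "events.csv"
    if not ev_path.exists():
        raise FormatError(f"missing file: {ev_path}")
    events = pd.read_csv(ev_path, dtype={"time_s": float, "current_uA": float,
                                         "site_id": str})
    expected_cols = ["time_s", "current_uA", "site_id"]
    if list(events.columns) != expected_cols:
        raise FormatError(
            f"ill-formed file: {ev_path}: expected columns {expected_cols}"
        )

    session = RecordingSession(
        sampling_rate=float(meta["sampling_rate"]),
        channels=channels,
        units=units,
        events=events,
        protocol=StimulationProtocol(**meta["protocol"]),
        metadata=meta["metadata"],
    )
    try:
        session.validate()
    except ParameterError as exc:
        raise ValidationError(str(exc)) from exc
    lengths = {name: len(v) for name, v in channels.items()}
    if len(set(lengths.values())) != 1:
        raise ValidationError(f"unequal channel lengths: {lengths}")
    return session


def write_ground_truth(truth: GroundTruth, path) -> None:
    payload = {
        "entries": [
            {
                "site_id": e.site_id,
                "channel": e.channel,
                "latency_ms": e.latency_ms,
                "threshold_ua": e.threshold_ua,
                "gain_effective": e.gain_effective,
                "pulse_amplitudes": np.asarray(e.pulse_amplitudes).tolist(),
            }
            for e in truth.entries.values()
        ],
        "burst_intervals": {k: list(v) for k, v in truth.burst_intervals.items()},
        "expected_percent": [
            {"site_id": s, "channel": c, "percent": p}
            for (s, c), p in truth.expected_percent.items()
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_ground_truth(path) -> GroundTruth:
    p = Path(path)
    if not p.exists():
        raise FormatError(f"missing file: {p}")
    payload = json.loads(p.read_text())
    entries = {
        (e["site_id"], e["channel"]): SiteChannelTruth(
            site_id=e["site_id"],
            channel=e["channel"],
            latency_ms=e["latency_ms"],
            threshold_ua=e["threshold_ua"],
            gain_effective=e["gain_effective"],
            pulse_amplitudes=np.asarray(e["pulse_amplitudes"]),
        )
        for e in payload["entries"]
    }
    return GroundTruth(
        entries=entries,
        burst_intervals={k: tuple(v) for k, v in
                         payload.get("burst_intervals", {}).items()},
        expected_percent={(e["site_id"], e["channel"]): e["percent"]
                          for e in payload.get("expected_percent", [])},
    )
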