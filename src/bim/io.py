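"""Core domain types and on-disk formats for multichannel bioimpedance recordings.

A recording bundle is a directory containing four plain-text artifacts:

``channels.csv``
    Long-format impedance samples: ``channel, t_s, z_ohm, quality``.
``icp.csv``
    Intracranial pressure: ``t_s, icp_mmhg``.
``events.csv``
    Sync/annotation markers: ``label, t_s, duration_s``.
``meta.json``
    Subject id, seed, schema version and free-form metadata.

Times are seconds as float from recording start (t = 0 at start of
baseline). Impedance is stored as magnitude in ohms; the complex
Z = R + jX measured by a tetrapolar system is carried as |Z| only, since
the monitor reports the voltage/current amplitude ratio.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("bim")

SCHEMA_VERSION = 1

#: Number of multiplexed impedance channels.
N_CHANNELS = 8
#: Seconds each channel stays active before the multiplexer advances.
SLOT_S = 10.0
#: Full multiplexing cycle (all channels visited once).
CYCLE_S = SLOT_S * N_CHANNELS

PHASE_NAMES = (
    "baseline",
    "inflation",
    "deflation",
    "hematoma",
    "global_osmotic",
    "global_terminal",
)

FOCAL_PHASES = ("inflation", "deflation", "hematoma")
GLOBAL_PHASES = ("global_osmotic", "global_terminal")


class ValidationError(ValueError):
    """A domain object violates one of its invariants."""


class FormatError(ValueError):
    """An on-disk bundle is malformed."""


class PipelineError(RuntimeError):
    """A downstream stage cannot proceed (e.g. no usable traces left)."""


# ---------------------------------------------------------------------------
# Channel traces and recordings
# ---------------------------------------------------------------------------

@dataclass
class ChannelTrace:
    """Impedance samples for one multiplexed channel.

    Samples only exist inside the channel's active 10 s slots; the
    ``quality_mask`` marks samples usable for analysis (False inside CT
    bursts, after unrepaired step artifacts, ...).
    """

    channel_id: int
    timestamps: np.ndarray
    impedance: np.ndarray
    quality_mask: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.impedance = np.asarray(self.impedance, dtype=float)
        self.quality_mask = np.asarray(self.quality_mask, dtype=bool)

    def validate(self) -> None:
        if not (1 <= int(self.channel_id) <= N_CHANNELS):
            raise ValidationError(
                f"channel_id must be in 1..{N_CHANNELS}, got {self.channel_id}"
            )
        n = len(self.timestamps)
        if len(self.impedance) != n or len(self.quality_mask) != n:
            raise ValidationError(
                f"channel {self.channel_id}: field lengths differ"
            )
        if n > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValidationError(
                f"channel {self.channel_id}: timestamps not strictly increasing"
            )
        if n and not np.all(np.isfinite(self.impedance[self.quality_mask])):
            raise ValidationError(
                f"channel {self.channel_id}: non-finite impedance where usable"
            )

    def copy(self) -> "ChannelTrace":
        return ChannelTrace(
            self.channel_id,
            self.timestamps.copy(),
            self.impedance.copy(),
            self.quality_mask.copy(),
        )

    def usable(self) -> "ChannelTrace":
        """Return a view restricted to usable samples."""
        m = self.quality_mask
        return ChannelTrace(
            self.channel_id, self.timestamps[m], self.impedance[m],
            np.ones(int(m.sum()), dtype=bool),
        )

    def slot_means(self, slot_s: float = SLOT_S):
        """Aggregate usable samples into per-slot means.

        Returns ``(midpoints, means, counts)`` where each slot is one
        contiguous 10 s active window of this channel. Slots with no usable
        sample are dropped. The result is cached: traces are frozen once
        analysis starts (filtering only rewrites masks on copies).
        """
        cache = self.__dict__.setdefault("_slot_cache", {})
        if slot_s in cache:
            return cache[slot_s]
        out = self._slot_means(slot_s)
        cache[slot_s] = out
        return out

    def _slot_means(self, slot_s: float):
        t, z, q = self.timestamps, self.impedance, self.quality_mask
        if len(t) == 0:
            return np.array([]), np.array([]), np.array([], dtype=int)
        # Slot index from absolute time: channel c occupies
        # [k*80 + (c-1)*10, +10) for integer cycle k.
        idx = np.floor(t / slot_s).astype(np.int64)
        # group by slot index, usable samples only
        order = np.argsort(idx, kind="stable")
        idx_s, t_s, z_s, q_s = idx[order], t[order], z[order], q[order]
        keep = q_s
        idx_s, t_s, z_s = idx_s[keep], t_s[keep], z_s[keep]
        if len(idx_s) == 0:
            return np.array([]), np.array([]), np.array([], dtype=int)
        uniq, start = np.unique(idx_s, return_index=True)
        sums = np.add.reduceat(z_s, start)
        counts = np.diff(np.append(start, len(z_s)))
        means = sums / counts
        mids = (uniq + 0.5) * slot_s
        return mids, means, counts


@dataclass
class SyncEvent:
    """A timestamped annotation (phase start, volume step, CT, ICC check)."""

    label: str
    time_s: float
    duration_s: float = 0.0


@dataclass
class MultiChannelRecording:
    """One subject's full recording: 8 impedance traces, ICP and markers."""

    traces: list  # list[ChannelTrace], exactly 8, distinct channel ids
    icp_time: np.ndarray
    icp: np.ndarray
    sync_events: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.icp_time = np.asarray(self.icp_time, dtype=float)
        self.icp = np.asarray(self.icp, dtype=float)
        self.metadata.setdefault("schema_version", SCHEMA_VERSION)

    def trace(self, channel_id: int) -> ChannelTrace:
        for tr in self.traces:
            if tr.channel_id == channel_id:
                return tr
        raise KeyError(channel_id)

    def span(self):
        t0 = min(tr.timestamps[0] for tr in self.traces if len(tr.timestamps))
        t1 = max(tr.timestamps[-1] for tr in self.traces if len(tr.timestamps))
        return float(t0), float(t1)

    def events(self, label: str):
        return [e for e in self.sync_events if e.label == label or
                e.label.startswith(label + ":")]

    def validate(self) -> None:
        if len(self.traces) != N_CHANNELS:
            raise ValidationError(
                f"expected {N_CHANNELS} channels, got {len(self.traces)}"
            )
        ids = sorted(tr.channel_id for tr in self.traces)
        if ids != list(range(1, N_CHANNELS + 1)):
            raise ValidationError(f"channel ids must be 1..8, got {ids}")
        for tr in self.traces:
            tr.validate()
        if len(self.icp_time) != len(self.icp):
            raise ValidationError("icp arrays length mismatch")
        t0, t1 = self.span()
        for ev in self.sync_events:
            if not (t0 - CYCLE_S <= ev.time_s <= t1 + CYCLE_S):
                raise ValidationError(
                    f"sync event {ev.label!r} at {ev.time_s}s outside span"
                )
        # multiplexing: one channel active at a time
        for tr in self.traces:
            if len(tr.timestamps) == 0:
                continue
            slot = np.floor(tr.timestamps / SLOT_S).astype(np.int64)
            if not np.all(slot % N_CHANNELS == tr.channel_id - 1):
                raise ValidationError(
                    f"channel {tr.channel_id}: samples outside its 10 s slots"
                )

    def copy(self) -> "MultiChannelRecording":
        return MultiChannelRecording(
            [tr.copy() for tr in self.traces],
            self.icp_time.copy(),
            self.icp.copy(),
            [replace(e) for e in self.sync_events],
            dict(self.metadata),
        )


# ---------------------------------------------------------------------------
# Injury protocol
# ---------------------------------------------------------------------------

@dataclass
class PhaseSpec:
    """One protocol phase: stepped (volume injections) or unstepped."""

    name: str
    step_volume_ml: float = 0.0
    step_interval_s: float = 0.0
    n_steps: int = 0
    duration_s: float = 0.0

    def __post_init__(self) -> None:
        if self.n_steps and not self.duration_s:
            self.duration_s = self.n_steps * self.step_interval_s

    @property
    def total_volume_ml(self) -> float:
        return self.step_volume_ml * self.n_steps

    def validate(self) -> None:
        if self.name not in PHASE_NAMES:
            raise ValidationError(f"unknown phase name {self.name!r}")
        if self.step_volume_ml < 0 or self.duration_s <= 0:
            raise ValidationError(f"phase {self.name}: negative volume/duration")
        if self.n_steps:
            if self.step_interval_s <= 0:
                raise ValidationError(
                    f"phase {self.name}: step_interval must be positive"
                )


@dataclass
class EventWindow:
    """Static-volume window following one protocol step."""

    phase_name: str
    start_s: float
    end_s: float
    volume_at_end_ml: float

    def validate(self) -> None:
        if not self.start_s < self.end_s:
            raise ValidationError("event window start must precede end")

    @property
    def midpoint_s(self) -> float:
        return 0.5 * (self.start_s + self.end_s)


@dataclass
class InjuryProtocol:
    """Ordered schedule of phases.

    The default reproduces the porcine study protocol: 30 min baseline,
    balloon inflation in 100 µL steps every 5 min to 1.2 mL, mirrored
    deflation over 1 h, autologous-blood injection in 200 µL steps every
    5 min to 1.2 mL, a global osmotic (mannitol) phase, and a global
    terminal (euthanasia) phase.
    """

    phases: list  # list[PhaseSpec]

    def validate(self) -> None:
        if not self.phases:
            raise ValidationError("protocol has no phases")
        for p in self.phases:
            p.validate()

    def phase(self, name: str) -> PhaseSpec:
        for p in self.phases:
            if p.name == name:
                return p
        raise KeyError(name)

    def phase_names(self):
        return [p.name for p in self.phases]

    def phase_start(self, name: str) -> float:
        t = 0.0
        for p in self.phases:
            if p.name == name:
                return t
            t += p.duration_s
        raise KeyError(name)

    def phase_window(self, name: str):
        t0 = self.phase_start(name)
        return t0, t0 + self.phase(name).duration_s

    @property
    def total_duration_s(self) -> float:
        return sum(p.duration_s for p in self.phases)

    def step_times(self, name: str):
        """Absolute times of the volume steps of a stepped phase."""
        p = self.phase(name)
        t0 = self.phase_start(name)
        return [t0 + i * p.step_interval_s for i in range(p.n_steps)]

    def event_windows(self, name: str):
        """Static-volume windows (one per step) for a stepped phase."""
        p = self.phase(name)
        sign = -1.0 if name == "deflation" else 1.0
        v0 = p.total_volume_ml if name == "deflation" else 0.0
        out = []
        for i, t in enumerate(self.step_times(name)):
            v = v0 + sign * (i + 1) * p.step_volume_ml
            out.append(EventWindow(name, t, t + p.step_interval_s, v))
        return out

    def balloon_volume(self, t) -> np.ndarray:
        """Cumulative balloon volume (mL) at times ``t``."""
        t = np.asarray(t, dtype=float)
        v = np.zeros_like(t)
        for name, sign in (("inflation", 1.0), ("deflation", -1.0)):
            try:
                p = self.phase(name)
            except KeyError:
                continue
            for st in self.step_times(name):
                v = v + sign * p.step_volume_ml * (t >= st)
        return v

    def blood_volume(self, t) -> np.ndarray:
        """Cumulative injected blood-analog volume (mL) at times ``t``."""
        t = np.asarray(t, dtype=float)
        v = np.zeros_like(t)
        try:
            p = self.phase("hematoma")
        except KeyError:
            return v
        for st in self.step_times("hematoma"):
            v = v + p.step_volume_ml * (t >= st)
        return v


def default_protocol() -> InjuryProtocol:
    """The study's injury schedule (times in seconds, volumes in mL)."""
    return InjuryProtocol([
        PhaseSpec("baseline", duration_s=1800.0),
        PhaseSpec("inflation", 0.1, 300.0, 12),
        PhaseSpec("deflation", 0.1, 300.0, 12),
        PhaseSpec("hematoma", 0.2, 300.0, 6),
        PhaseSpec("global_osmotic", duration_s=1800.0),
        PhaseSpec("global_terminal", duration_s=1200.0),
    ])


def load_protocol(config=None) -> InjuryProtocol:
    """Build a protocol from structured config (dict, YAML/TOML text or path).

    Absent phases take the default schedule; a phase entry overrides only
    the fields it declares. ``config=None`` or an empty mapping returns the
    default protocol.
    """
    data = _load_config(config)
    proto = default_protocol()
    if not data:
        proto.validate()
        return proto
    phases = data.get("phases", data)
    by_name = {p.name: p for p in proto.phases}
    if isinstance(phases, dict):
        items = phases.items()
    else:  # list of {name: ..., ...}
        items = [(d["name"], {k: v for k, v in d.items() if k != "name"})
                 for d in phases]
    for name, fields_ in items:
        if name not in by_name:
            raise ValidationError(f"unknown phase {name!r}")
        p = by_name[name]
        mapping = {
            "step_volume_ml": "step_volume_ml",
            "step_volume": "step_volume_ml",
            "step_interval_s": "step_interval_s",
            "step_interval": "step_interval_s",
            "n_steps": "n_steps",
            "duration_s": "duration_s",
            "duration": "duration_s",
        }
        for key, value in dict(fields_).items():
            if key not in mapping:
                raise ValidationError(f"phase {name}: unknown field {key!r}")
            setattr(p, mapping[key], value)
        if p.n_steps:
            p.duration_s = p.n_steps * p.step_interval_s
    proto.validate()
    return proto


def _load_config(config):
    """Accept None, dict, YAML/TOML text, or a path to a .yaml/.yml/.toml file."""
    if config is None:
        return {}
    if isinstance(config, dict):
        return config
    import os
    text = None
    if isinstance(config, (str, bytes)) and os.path.exists(str(config)):
        path = str(config)
        if path.endswith(".toml"):
            import tomllib
            with open(path, "rb") as fh:
                return tomllib.load(fh)
        with open(path) as fh:
            text = fh.read()
    else:
        text = config
    data = yaml.safe_load(text)
    return data or {}


# ---------------------------------------------------------------------------
# Bundle I/O
# ---------------------------------------------------------------------------

_REQUIRED_CHANNEL_COLS = ("channel", "t_s", "z_ohm", "quality")
_FLOAT_FMT = "%.6f"


def write_recording(recording: MultiChannelRecording, path) -> None:
    """Write a recording bundle (directory of CSV + JSON) to ``path``."""
    from pathlib import Path

    recording.validate()
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    frames = []
    for tr in recording.traces:
        frames.append(pd.DataFrame({
            "channel": tr.channel_id,
            "t_s": tr.timestamps,
            "z_ohm": tr.impedance,
            "quality": tr.quality_mask.astype(int),
        }))
    pd.concat(frames, ignore_index=True).to_csv(
        p / "channels.csv", index=False, float_format=_FLOAT_FMT)
    pd.DataFrame({"t_s": recording.icp_time, "icp_mmhg": recording.icp}
                 ).to_csv(p / "icp.csv", index=False, float_format=_FLOAT_FMT)
    pd.DataFrame(
        [{"label": e.label, "t_s": e.time_s, "duration_s": e.duration_s}
         for e in recording.sync_events],
        columns=["label", "t_s", "duration_s"],
    ).to_csv(p / "events.csv", index=False, float_format=_FLOAT_FMT)
    with open(p / "meta.json", "w") as fh:
        json.dump(recording.metadata, fh, indent=2, default=str)


def read_recording(path) -> MultiChannelRecording:
    """Read a bundle written by :func:`write_recording`."""
    from pathlib import Path

    p = Path(path)
    ch_path = p / "channels.csv"
    if not ch_path.exists():
        raise FormatError(f"not a recording bundle: {path} (channels.csv missing)")
    df = pd.read_csv(ch_path)
    for col in _REQUIRED_CHANNEL_COLS:
        if col not in df.columns:
            raise FormatError(f"channels.csv: missing required column {col!r}")
    extra = set(df.columns) - set(_REQUIRED_CHANNEL_COLS)
    if extra:
        logger.warning("channels.csv: ignoring unknown columns %s", sorted(extra))
    traces = []
    for cid, grp in df.groupby("channel", sort=True):
        tr = ChannelTrace(
            int(cid),
            grp["t_s"].to_numpy(),
            grp["z_ohm"].to_numpy(),
            grp["quality"].to_numpy().astype(bool),
        )
        if len(tr.timestamps) > 1 and not np.all(np.diff(tr.timestamps) > 0):
            raise ValidationError(
                f"channel {cid}: non-monotone timestamps in channels.csv")
        traces.append(tr)
    icp_df = pd.read_csv(p / "icp.csv")
    for col in ("t_s", "icp_mmhg"):
        if col not in icp_df.columns:
            raise FormatError(f"icp.csv: missing required column {col!r}")
    ev_df = pd.read_csv(p / "events.csv")
    events = [SyncEvent(str(r.label), float(r.t_s), float(r.duration_s))
              for r in ev_df.itertuples()]
    with open(p / "meta.json") as fh:
        meta = json.load(fh)
    rec = MultiChannelRecording(
        traces, icp_df["t_s"].to_numpy(), icp_df["icp_mmhg"].to_numpy(),
        events, meta)
    rec.validate()
    return rec
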