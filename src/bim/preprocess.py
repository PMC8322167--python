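"""Artifact filtering, quality exclusion and baseline de-trending.

Filtering is mask-only: unusable samples are flagged, never altered or
interpolated (interpolation would manufacture data inside CT bursts).
Three artifact classes are handled, each with explicit configurable
thresholds and an exclusion reason in the quality report:

* CT bursts — broadband noise while the scanner is active; the burst
  window (plus a pad) is masked on all channels;
* DC shifts — abrupt persistent offsets (e.g. a compromised cable or
  amplifier step) found by a median-of-adjacent-windows detector;
* compromised electrodes — channel-phase traces that lose too many
  samples or accumulate unrepaired steps are excluded outright.

De-trending follows the study rule: a least-squares line fitted to the
final 10 min of baseline is extrapolated and subtracted ahead of the
inflation metrics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import (
    ChannelTrace,
    MultiChannelRecording,
    PipelineError,
    ValidationError,
)

logger = logging.getLogger("bim")

CT_PAD_S = 5.0
#: Step-detector window: one full multiplexing cycle, so each window holds
#: exactly one 10 s active slot of the channel despite the 80 s gaps
#: between a channel's active periods.
STEP_WINDOW_S = 80.0
STEP_THRESHOLD_OHM = 20.0
MAX_MASKED_FRACTION = 0.5
MAX_UNREPAIRED_STEPS = 1
BASELINE_FIT_WINDOW_S = 600.0


class BaselineError(PipelineError):
    """Baseline window unusable; run without de-trending."""


@dataclass
class ChannelQuality:
    channel_id: int
    phase_name: str
    fraction_masked: float
    n_dc_shifts: int
    excluded: bool
    exclusion_reason: str = ""


@dataclass
class QualityReport:
    """Per channel-phase quality assessment after filtering."""

    entries: list = field(default_factory=list)

    def excluded(self, phase_name: str):
        return [e.channel_id for e in self.entries
                if e.phase_name == phase_name and e.excluded]

    def usable_channels(self, phase_name: str):
        return [e.channel_id for e in self.entries
                if e.phase_name == phase_name and not e.excluded]

    def is_usable(self, channel_id: int, phase_name: str) -> bool:
        for e in self.entries:
            if e.channel_id == channel_id and e.phase_name == phase_name:
                return not e.excluded
        return True

    def to_dict(self):
        return [vars(e) for e in self.entries]


def flag_ct_windows(recording: MultiChannelRecording,
                    pad_s: float = CT_PAD_S) -> MultiChannelRecording:
    """Mask samples inside CT acquisition windows (± pad) on all channels.

    Returns a copy; the input recording is untouched. No CT markers is a
    no-op.
    """
    rec = recording.copy()
    cts = [e for e in rec.sync_events if e.label == "ct"]
    for tr in rec.traces:
        for ev in cts:
            lo = ev.time_s - pad_s
            hi = ev.time_s + ev.duration_s + pad_s
            tr.quality_mask &= ~((tr.timestamps >= lo) & (tr.timestamps <= hi))
    return rec


def detect_step_artifacts(trace: ChannelTrace, window_s: float = STEP_WINDOW_S,
                          step_threshold_ohm: float = STEP_THRESHOLD_OHM,
                          protocol_step_times=(), guard_s: float = None):
    """Detect abrupt DC shifts in one channel trace; mask what follows.

    A step is flagged at a candidate time ``t`` when
    ``|median(z in [t, t+window]) − median(z in [t−window, t])|`` exceeds
    the threshold — medians over windows are robust to the 80 s
    multiplexing gaps — *unless* ``t`` falls within the guard of a protocol
    volume step (protocol-synchronous changes are signal, not artifact).
    Samples at and after the first flagged step are masked (the step is
    left unrepaired).

    Returns ``(detections, trace)`` where detections is a list of
    ``(time, magnitude)`` and ``trace`` a masked copy.
    """
    t_all = trace.timestamps
    if len(t_all) < 2:
        return [], trace.copy()
    usable = trace.quality_mask
    t = t_all[usable]
    z = trace.impedance[usable]
    if len(t) < 2:
        return [], trace.copy()
    if guard_s is None:
        guard_s = max(window_s, 300.0)
    # candidate times: starts of this channel's active slots (gaps > 2x
    # median sample spacing delimit slots)
    dt = np.diff(t)
    spacing = np.median(dt)
    starts = np.concatenate(([0], np.nonzero(dt > 2.0 * spacing)[0] + 1))
    cand = t[starts[1:]] if len(starts) > 1 else np.array([])
    detections = []
    out = trace.copy()
    step_times = np.asarray(list(protocol_step_times), dtype=float)
    for tc in cand:
        left = z[(t >= tc - window_s - 1e-9) & (t < tc)]
        right = z[(t >= tc) & (t < tc + window_s + 1e-9)]
        if len(left) == 0 or len(right) == 0:
            continue
        mag = float(np.median(right) - np.median(left))
        if abs(mag) <= step_threshold_ohm:
            continue
        if len(step_times) and np.min(np.abs(step_times - tc)) <= guard_s:
            continue  # synchronous with an injection: injury signal
        detections.append((float(tc), mag))
    if detections:
        first = detections[0][0]
        out.quality_mask &= out.timestamps < first
        logger.info("channel %d: %d step artifact(s); masking after t=%.1fs",
                    trace.channel_id, len(detections), first)
    return detections, out


def apply_quality_exclusion(recording: MultiChannelRecording, phase_windows,
                            max_masked_fraction: float = MAX_MASKED_FRACTION,
                            max_unrepaired_steps: int = MAX_UNREPAIRED_STEPS,
                            step_detections=None) -> QualityReport:
    """Per channel-phase exclusion of traces failing the quality metrics.

    ``phase_windows`` maps phase name -> (start, end). A channel-phase
    trace is excluded when its masked fraction exceeds
    ``max_masked_fraction`` or its unrepaired step count exceeds
    ``max_unrepaired_steps``. Raises :class:`PipelineError` if every
    channel of a phase is excluded.
    """
    step_detections = step_detections or {}
    report = QualityReport()
    for phase_name, (lo, hi) in phase_windows.items():
        n_excluded = 0
        for tr in recording.traces:
            inside = (tr.timestamps >= lo) & (tr.timestamps < hi)
            n = int(inside.sum())
            if n == 0:
                frac = 1.0
            else:
                frac = 1.0 - float(tr.quality_mask[inside].sum()) / n
            steps = [s for s, _ in step_detections.get(tr.channel_id, [])
                     if lo <= s < hi]
            excluded = False
            reason = ""
            if frac > max_masked_fraction:
                excluded, reason = True, (
                    f"masked fraction {frac:.2f} > {max_masked_fraction}")
            elif len(steps) > max_unrepaired_steps:
                excluded, reason = True, (
                    f"{len(steps)} unrepaired steps > {max_unrepaired_steps}")
            n_excluded += excluded
            report.entries.append(ChannelQuality(
                tr.channel_id, phase_name, frac, len(steps), excluded, reason))
        if n_excluded == len(recording.traces):
            raise PipelineError(f"phase unusable: all channels excluded "
                                f"for {phase_name!r}")
    return report


def detrend_baseline(trace: ChannelTrace, baseline_end_s: float,
                     fit_window_s: float = BASELINE_FIT_WINDOW_S,
                     apply_span=None):
    """Subtract a linear fit of the late-baseline trend from the trace.

    The line is fitted by least squares to usable samples in the final
    ``fit_window_s`` of baseline (``[baseline_end − window, baseline_end)``)
    and its extrapolation subtracted over ``apply_span`` (default: the whole
    trace). This removes the systemic settling response to instrumentation
    so that impedance change isolates the injury.

    Returns ``(detrended_trace, (slope, intercept))``; raises
    :class:`BaselineError` with fewer than 2 usable fit samples (the
    analysis then falls back to non-detrended change).
    """
    m = (trace.quality_mask
         & (trace.timestamps >= baseline_end_s - fit_window_s)
         & (trace.timestamps < baseline_end_s))
    if int(m.sum()) < 2:
        raise BaselineError(
            f"channel {trace.channel_id}: baseline unusable; "
            "run without de-trending")
    tf = trace.timestamps[m]
    zf = trace.impedance[m]
    slope, intercept = np.polyfit(tf, zf, 1)
    out = trace.copy()
    if apply_span is None:
        sel = np.ones(len(out.timestamps), dtype=bool)
    else:
        lo, hi = apply_span
        sel = (out.timestamps >= lo) & (out.timestamps < hi)
    out.impedance = out.impedance.astype(float)
    out.impedance[sel] -= slope * out.timestamps[sel] + intercept
    return out, (float(slope), float(intercept))


def preprocess_recording(recording: MultiChannelRecording, protocol,
                         ct_pad_s: float = CT_PAD_S,
                         step_window_s: float = STEP_WINDOW_S,
                         step_threshold_ohm: float = STEP_THRESHOLD_OHM,
                         max_masked_fraction: float = MAX_MASKED_FRACTION,
                         max_unrepaired_steps: int = MAX_UNREPAIRED_STEPS):
    """Full filtering pass: CT masking, step artifacts, quality exclusion.

    Returns ``(filtered_recording, quality_report, step_detections)``.
    """
    rec = flag_ct_windows(recording, ct_pad_s)
    # impedance changes synchronous with any protocol intervention — a
    # volume step or a phase onset (mannitol, euthanasia) — are signal
    step_times = []
    for name in ("inflation", "deflation", "hematoma"):
        if name in protocol.phase_names():
            step_times.extend(protocol.step_times(name))
    step_times.extend(protocol.phase_start(p.name)
                      for p in protocol.phases if p.name != "baseline")
    detections = {}
    new_traces = []
    for tr in rec.traces:
        det, masked = detect_step_artifacts(
            tr, step_window_s, step_threshold_ohm, step_times)
        detections[tr.channel_id] = det
        new_traces.append(masked)
    rec.traces = new_traces
    windows = {p.name: protocol.phase_window(p.name) for p in protocol.phases}
    report = apply_quality_exclusion(
        rec, windows, max_masked_fraction, max_unrepaired_steps, detections)
    return rec, report, detections
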