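"""Carrier-level signal to impedance: matched-filter amplitude demodulation.

The monitor injects a sinusoidal current (2.3 mA peak-to-peak at 50 kHz in
hardware) and measures the induced voltage with a separate electrode pair.
Each 20 ms block of carrier samples is correlated against reference
quadrature sinusoids (a matched filter, the optimal amplitude estimator in
white noise); impedance is the ratio of the voltage and current amplitudes,
yielding a 50 Hz impedance stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ChannelTrace, ValidationError

#: Demodulation block length in seconds (1000 samples at the hardware's
#: stated rate; expressed in time so other simulation rates still produce
#: a 50 Hz impedance stream).
BLOCK_S = 0.02

#: Current amplitudes below this floor flag the sample unusable instead of
#: producing a near-infinite ratio (well below the 0.5–5.0 mA drive range).
CURRENT_FLOOR_A = 1e-6


@dataclass
class RawAcquisition:
    """Simultaneously sampled voltage/current carrier streams.

    ``channel_schedule`` lists ``(channel_id, start_sample, end_sample)``
    half-open slots assigning sample ranges to multiplexed channels.
    """

    voltage_samples: np.ndarray
    current_samples: np.ndarray
    f_carrier: float
    f_sample: float
    channel_schedule: list = field(default_factory=list)

    def validate(self) -> None:
        v = np.asarray(self.voltage_samples)
        i = np.asarray(self.current_samples)
        if v.shape != i.shape:
            raise ValidationError("voltage/current sample arrays differ in length")
        slots = sorted(self.channel_schedule, key=lambda s: s[1])
        for (c0, a0, b0), (c1, a1, b1) in zip(slots, slots[1:]):
            if a1 < b0:
                raise ValidationError("channel schedule slots overlap")
        for c, a, b in slots:
            if not (0 <= a < b <= len(v)):
                raise ValidationError(f"schedule slot ({c},{a},{b}) out of range")


def matched_filter_amplitude(block, f_carrier: float, f_sample: float) -> float:
    """Carrier amplitude of ``block`` by quadrature correlation.

    ``A = (2/N)·sqrt((Σ x·cos ωk)² + (Σ x·sin ωk)²)`` with
    ``ω = 2π f_carrier / f_sample`` — phase-invariant, exact for an
    integer number of carrier cycles.
    """
    x = np.asarray(block, dtype=float)
    if f_sample < 4.0 * f_carrier:
        raise ValidationError(
            f"f_sample={f_sample} < 4×f_carrier: carrier aliases")
    n = len(x)
    if n < 2.0 * f_sample / f_carrier:
        raise ValidationError(
            f"block of {n} samples is shorter than 2 carrier cycles")
    k = np.arange(n)
    w = 2.0 * np.pi * f_carrier / f_sample
    c = float(np.dot(x, np.cos(w * k)))
    s = float(np.dot(x, np.sin(w * k)))
    return (2.0 / n) * float(np.hypot(c, s))


def compute_impedance_series(raw: RawAcquisition, block_s: float = BLOCK_S,
                             current_floor_a: float = CURRENT_FLOOR_A):
    """Demodulate a raw acquisition into per-channel impedance traces.

    Within each schedule slot the samples are cut into ``block_s`` blocks
    (partial trailing blocks dropped to avoid edge amplitude bias); each
    block yields one impedance sample Z = A_V / A_I timestamped at the
    block midpoint. Blocks whose current amplitude falls below the floor
    are emitted with ``quality_mask`` False.
    """
    raw.validate()
    n_block = int(round(block_s * raw.f_sample))
    per_channel: dict = {}
    v = np.asarray(raw.voltage_samples, dtype=float)
    i = np.asarray(raw.current_samples, dtype=float)
    for channel_id, a, b in sorted(raw.channel_schedule, key=lambda s: s[1]):
        n_blocks = (b - a) // n_block
        for j in range(int(n_blocks)):
            lo = a + j * n_block
            hi = lo + n_block
            a_v = matched_filter_amplitude(v[lo:hi], raw.f_carrier, raw.f_sample)
            a_i = matched_filter_amplitude(i[lo:hi], raw.f_carrier, raw.f_sample)
            t_mid = (lo + hi) / 2.0 / raw.f_sample
            ts, zs, qs = per_channel.setdefault(channel_id, ([], [], []))
            ts.append(t_mid)
            if a_i < current_floor_a:
                zs.append(np.nan)
                qs.append(False)
            else:
                zs.append(a_v / a_i)
                qs.append(True)
    traces = []
    for channel_id, (ts, zs, qs) in sorted(per_channel.items()):
        traces.append(ChannelTrace(
            channel_id, np.asarray(ts), np.asarray(zs),
            np.asarray(qs, dtype=bool)))
    return traces
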