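"""Artifact masking, step detection, quality exclusion, de-trending."""

import numpy as np
import pytest

from bim import (
    ChannelTrace,
    PipelineError,
    SyncEvent,
    apply_quality_exclusion,
    detect_step_artifacts,
    detrend_baseline,
    flag_ct_windows,
    preprocess_recording,
    synthesize_recording,
)
from bim.preprocess import BaselineError
from bim.simulate import ArtifactSpec
from tests.conftest import clean_scenario


def slot_trace(channel_id=1, n_cycles=40, rate=5.0, values=None):
    """A synthetic single-channel trace on the multiplexing grid."""
    from bim.simulate import channel_slot_times
    t = channel_slot_times(channel_id, n_cycles * 80.0, rate)
    z = np.full(len(t), 1000.0) if values is None else values(t)
    return ChannelTrace(channel_id, t, z, np.ones(len(t), dtype=bool))


class TestCtMasking:
    def test_no_ct_events_is_noop(self, clean_recording):
        out = flag_ct_windows(clean_recording.copy())
        # clean scenario has an empty artifact spec -> no "ct" events
        assert all(tr.quality_mask.all() for tr in out.traces)

    def test_exact_span_masked(self, clean_recording):
        rec = clean_recording.copy()
        rec.sync_events.append(SyncEvent("ct", 400.0, 30.0))
        out = flag_ct_windows(rec, pad_s=5.0)
        # 30 s burst + 5 s pad either side: exactly the 40 s span [395, 435]
        for tr in out.traces:
            bad = ~tr.quality_mask
            if bad.any():
                assert tr.timestamps[bad].min() >= 395.0
                assert tr.timestamps[bad].max() <= 435.0
            inside = (tr.timestamps >= 395.0) & (tr.timestamps <= 435.0)
            assert not tr.quality_mask[inside].any()

    def test_mask_only_contract(self, clean_recording):
        rec = clean_recording.copy()
        rec.sync_events.append(SyncEvent("ct", 400.0, 30.0))
        out = flag_ct_windows(rec)
        for a, b in zip(clean_recording.traces, out.traces):
            np.testing.assert_array_equal(a.impedance, b.impedance)

    def test_post_filter_noise_near_ground_truth(self, default_scenario):
        """After masking the CT bursts the residual baseline noise matches
        the scenario's noise level within 10%."""
        sc = default_scenario
        rec = synthesize_recording(sc)
        out = flag_ct_windows(rec)
        sds = []
        for tr in out.traces:
            m = tr.quality_mask & (tr.timestamps < 1800.0)
            t, z = tr.timestamps[m], tr.impedance[m]
            d = np.diff(z)[np.isclose(np.diff(t), np.diff(t).min())]
            sds.append(np.std(d) / np.sqrt(2.0))
        assert np.mean(sds) == pytest.approx(sc.noise_sd_ohm, rel=0.10)


class TestStepDetection:
    def test_constant_trace_no_steps(self):
        det, _ = detect_step_artifacts(slot_trace())
        assert det == []

    def test_injected_dc_shift_found_and_masked(self):
        tr = slot_trace(values=lambda t: 1000.0 + 50.0 * (t >= 1200.0))
        det, masked = detect_step_artifacts(tr, step_threshold_ohm=20.0)
        assert len(det) == 1
        t_det, mag = det[0]
        assert abs(t_det - 1200.0) <= 80.0
        assert mag == pytest.approx(50.0, abs=1.0)
        assert not masked.quality_mask[masked.timestamps >= t_det].any()

    def test_protocol_synchronous_change_exempt(self):
        tr = slot_trace(values=lambda t: 1000.0 + 50.0 * (t >= 1200.0))
        det, _ = detect_step_artifacts(tr, step_threshold_ohm=20.0,
                                       protocol_step_times=[1200.0])
        assert det == []

    def test_subthreshold_change_ignored(self):
        tr = slot_trace(values=lambda t: 1000.0 + 10.0 * (t >= 1200.0))
        det, _ = detect_step_artifacts(tr, step_threshold_ohm=20.0)
        assert det == []


class TestQualityExclusion:
    def test_clean_recording_no_exclusions(self, clean_recording, protocol):
        _, report, _ = preprocess_recording(clean_recording, protocol)
        assert all(not e.excluded for e in report.entries)

    def test_saturating_droplet_excludes_one_trace(self, protocol):
        """A persistent droplet offset mid-baseline masks the channel from
        then on, so its later phase traces are excluded."""
        sc = clean_scenario(artifacts=ArtifactSpec(
            droplet_events=[(6, 1000.0, 400.0, 1e6)]))
        _, report, _ = preprocess_recording(
            synthesize_recording(sc), protocol)
        excluded = {(e.channel_id, e.phase_name)
                    for e in report.entries if e.excluded}
        assert (6, "hematoma") in excluded
        assert (6, "inflation") in excluded
        assert all(c == 6 for c, _ in excluded)

    def test_zero_thresholds_degenerate(self, clean_recording, protocol):
        windows = {p.name: protocol.phase_window(p.name)
                   for p in protocol.phases}
        fake_steps = {tr.channel_id: [(10.0, 99.0), (20.0, 99.0)]
                      for tr in clean_recording.traces}
        with pytest.raises(PipelineError, match="phase unusable"):
            apply_quality_exclusion(
                clean_recording, {"baseline": windows["baseline"]},
                max_masked_fraction=1.0, max_unrepaired_steps=0,
                step_detections=fake_steps)

    def test_exclusions_monotone_in_severity(self, protocol):
        """More corrupted channels -> at least as many exclusions."""
        counts = []
        for n_bad in (0, 1, 3):
            sc = clean_scenario(artifacts=ArtifactSpec(
                droplet_events=[(c, 900.0, 300.0, 1e6)
                                for c in range(1, n_bad + 1)]))
            _, report, _ = preprocess_recording(
                synthesize_recording(sc), protocol)
            counts.append(sum(e.excluded for e in report.entries))
        assert counts == sorted(counts)


class TestDetrend:
    def test_flat_baseline_intercept_only(self):
        tr = slot_trace()
        out, (slope, intercept) = detrend_baseline(tr, 1800.0)
        assert slope == pytest.approx(0.0, abs=1e-9)
        assert intercept == pytest.approx(1000.0)
        np.testing.assert_allclose(out.impedance, 0.0, atol=1e-6)

    def test_linear_drift_cancels_exactly(self):
        """36 Ω/h drift with no injury de-trends to ≈0 over inflation."""
        tr = slot_trace(n_cycles=70,
                        values=lambda t: 1000.0 + 36.0 * t / 3600.0)
        out, (slope, _) = detrend_baseline(tr, 1800.0)
        assert slope == pytest.approx(36.0 / 3600.0, rel=1e-9)
        after = out.timestamps >= 1800.0
        np.testing.assert_allclose(out.impedance[after], 0.0, atol=1e-9)

    def test_drifting_focal_recovery(self):
        """Drift + focal injury: de-trended nearest-channel ΔZ within 5%
        of focal_gain × 1.2 mL."""
        sc = clean_scenario(drift_linear_ohm_per_h=36.0, noise_sd_ohm=0.02)
        rec = synthesize_recording(sc)
        tr = rec.trace(sc.inclusion_sector)
        out, _ = detrend_baseline(tr, 1800.0)
        t_end = sc.protocol.phase_window("inflation")[1]
        m0 = (out.timestamps >= 1800.0 - 80.0) & (out.timestamps < 1800.0)
        m1 = (out.timestamps >= t_end - 80.0) & (out.timestamps < t_end)
        dz = out.impedance[m1].mean() - out.impedance[m0].mean()
        assert dz == pytest.approx(sc.focal_gain * 1.2, rel=0.05)

    def test_idempotent_on_own_output(self):
        tr = slot_trace(n_cycles=70,
                        values=lambda t: 1000.0 + 36.0 * t / 3600.0)
        once, _ = detrend_baseline(tr, 1800.0)
        twice, (slope2, icept2) = detrend_baseline(once, 1800.0)
        assert abs(slope2) < 1e-12 and abs(icept2) < 1e-9
        np.testing.assert_allclose(once.impedance, twice.impedance,
                                   atol=1e-9)

    def test_unusable_baseline_raises(self):
        tr = slot_trace()
        tr.quality_mask[tr.timestamps < 1800.0] = False
        with pytest.raises(BaselineError, match="without de-trending"):
            detrend_baseline(tr, 1800.0)
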