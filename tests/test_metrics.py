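"""Event metrics: window rules, ΔZ, DI, Pearson r and threshold detection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bim import (
    ChannelTrace,
    EventWindow,
    SyncEvent,
    ValidationError,
    delta_z,
    detect_volume_change,
    discriminatory_index,
    pearson_z_icp,
    step_impedance,
    synthesize_recording,
    zero_volume_impedance,
)
from bim.metrics import compute_event_metrics, step_deltas
from tests.conftest import clean_scenario


def slot_trace(channel_id=1, n_cycles=40, rate=5.0, values=None):
    from bim.simulate import channel_slot_times
    t = channel_slot_times(channel_id, n_cycles * 80.0, rate)
    z = np.full(len(t), 1000.0) if values is None else values(t)
    return ChannelTrace(channel_id, t, z, np.ones(len(t), dtype=bool))


class TestWindowRules:
    def test_zero_volume_constant_trace(self):
        assert zero_volume_impedance(slot_trace(), 1800.0) == 1000.0

    def test_zero_volume_respects_mask(self):
        # channel 1's slot inside [1720, 1800) is [1760, 1770); contaminate
        # and mask its second half (a CT burst, say)
        tr = slot_trace(values=lambda t: np.where(t >= 1765.0, 500.0, 1000.0))
        tr.quality_mask[tr.timestamps >= 1765.0] = False
        assert zero_volume_impedance(tr, 1800.0) == 1000.0

    def test_zero_volume_no_usable_samples_nan(self):
        tr = slot_trace()
        tr.quality_mask[:] = False
        assert np.isnan(zero_volume_impedance(tr, 1800.0))

    def test_step_picks_slot_nearest_window_middle(self):
        tr = slot_trace(values=lambda t: t)  # value identifies the slot
        win = EventWindow("inflation", 1800.0, 2100.0, 0.1)
        # channel 1 slots in [1800, 2100): 1840, 1920, 2000, 2080;
        # midpoints 1845, 1925, 2005, 2085; window middle 1950 -> 1925
        got = step_impedance(tr, win)
        assert got == pytest.approx(np.mean(np.arange(1920.0, 1930.0, 0.2)))

    def test_step_tie_breaks_to_earlier_slot(self):
        tr = slot_trace(values=lambda t: t)
        # both slot midpoints equidistant from the window middle at 1965
        win = EventWindow("inflation", 1880.0, 2050.0, 0.1)
        got = step_impedance(tr, win)
        assert got == pytest.approx(np.mean(np.arange(1920.0, 1930.0, 0.2)))

    def test_step_skips_icc_overlapping_slot(self):
        tr = slot_trace(values=lambda t: t)
        win = EventWindow("inflation", 1800.0, 2100.0, 0.1)
        icc = [SyncEvent("icc", 1918.0, 30.0)]  # covers the 1920 slot
        got = step_impedance(tr, win, icc_events=icc)
        assert got == pytest.approx(np.mean(np.arange(2000.0, 2010.0, 0.2)))

    def test_step_no_eligible_slot_nan(self):
        tr = slot_trace()
        win = EventWindow("inflation", 1801.0, 1805.0, 0.1)
        assert np.isnan(step_impedance(tr, win))


class TestDeltaAndDi:
    def test_delta_arithmetic(self):
        assert delta_z(1036.0, 1000.0) == 36.0
        assert np.isnan(delta_z(float("nan"), 1000.0))

    @pytest.mark.parametrize("dz,dicp,expect", [(10.0, 5.0, 2.0),
                                                (-6.0, 3.0, -2.0)])
    def test_di_values(self, dz, dicp, expect):
        assert discriminatory_index(dz, dicp) == expect

    def test_di_undefined_without_pressure_response(self):
        assert np.isnan(discriminatory_index(10.0, 0.05))

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(dz=st.floats(-1e3, 1e3), dicp=st.floats(0.2, 50.0))
    def test_di_antisymmetry(self, dz, dicp):
        assert discriminatory_index(-dz, dicp) == pytest.approx(
            -discriminatory_index(dz, dicp), abs=1e-12)

    def test_deflation_mirrors_inflation_noise_free(self):
        res = _clean_events()
        c = 2  # inclusion sector 3 -> index 2
        assert res["deflation"].delta_z[c] == pytest.approx(
            -res["inflation"].delta_z[c], rel=1e-6)

    def test_window_rule_robustness(self):
        """10 s slot rule vs full-window averaging agree on clean data."""
        sc = clean_scenario()
        rec = synthesize_recording(sc)
        tr = rec.trace(sc.inclusion_sector)
        proto = sc.protocol
        win = proto.event_windows("inflation")[-1]
        z_slot = step_impedance(tr, win)
        m_full = ((tr.timestamps >= win.start_s)
                  & (tr.timestamps < win.end_s))
        z_full = tr.impedance[m_full].mean()
        assert z_slot == pytest.approx(z_full, abs=1e-9)


class TestPearson:
    def test_perfect_linear_is_one(self):
        tr = slot_trace(values=lambda t: 2.0 * t + 1.0)
        icp_t = np.arange(0.0, 3200.0, 1.0)
        assert pearson_z_icp(tr, icp_t, icp_t) == pytest.approx(1.0)

    def test_anti_linear_is_minus_one(self):
        tr = slot_trace(values=lambda t: -t)
        icp_t = np.arange(0.0, 3200.0, 1.0)
        assert pearson_z_icp(tr, icp_t, icp_t) == pytest.approx(-1.0)

    def test_zero_variance_undefined(self):
        tr = slot_trace()  # constant impedance
        icp_t = np.arange(0.0, 3200.0, 1.0)
        assert np.isnan(pearson_z_icp(tr, icp_t, icp_t))

    def test_independent_noise_small_r(self, rng):
        """|r| of independent noise stays small across seeds: with 100
        paired slots, sd(r) ≈ 0.1, so |r| ≥ 0.3 is a 3-sigma event."""
        icp_t = np.arange(0.0, 8000.0, 1.0)
        big = 0
        for _ in range(50):
            tr = slot_trace(n_cycles=100,
                            values=lambda t: rng.normal(0, 1, len(t)))
            icp = rng.normal(20, 1, len(icp_t))
            big += abs(pearson_z_icp(tr, icp_t, icp)) >= 0.3
        assert big <= 1


class TestDetection:
    def _deltas(self, gain, n_steps=12, step=0.1):
        vols = np.arange(1, n_steps + 1) * step
        deltas = np.tile(gain * vols[:, None], (1, 8))
        return deltas, vols, np.arange(n_steps) * 300.0

    def test_analytic_first_crossing(self):
        """Gain 20 Ω/mL, 0.1 mL steps, 7.1 Ω threshold -> 0.4 mL."""
        deltas, vols, times = self._deltas(20.0)
        det = detect_volume_change(deltas, vols, times, 7.1, "mean-channel")
        assert det.detected and det.detection_volume_ml == pytest.approx(0.4)

    def test_zero_threshold_first_step(self):
        deltas, vols, times = self._deltas(20.0)
        det = detect_volume_change(deltas, vols, times, 0.0, "mean-channel")
        assert det.detection_volume_ml == pytest.approx(0.1)

    def test_never_crossed(self):
        deltas, vols, times = self._deltas(1.0)
        det = detect_volume_change(deltas, vols, times, 7.1, "mean-channel")
        assert not det.detected

    def test_closest_channel_requires_designation(self):
        deltas, vols, times = self._deltas(20.0)
        with pytest.raises(ValidationError, match="designated"):
            detect_volume_change(deltas, vols, times, 7.1, "closest-channel")

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(thr_lo=st.floats(0.1, 10.0), thr_hi=st.floats(10.0, 40.0))
    def test_monotone_in_threshold(self, thr_lo, thr_hi):
        """Lowering the threshold never delays detection."""
        deltas, vols, times = self._deltas(20.0)
        lo = detect_volume_change(deltas, vols, times, thr_lo, "mean-channel")
        hi = detect_volume_change(deltas, vols, times, thr_hi, "mean-channel")
        if hi.detected:
            assert lo.detected
            assert lo.detection_volume_ml <= hi.detection_volume_ml


_EVENTS_CACHE = {}


def _clean_events():
    """Per-phase EventMetrics on the clean noise-free recording (cached)."""
    if "res" not in _EVENTS_CACHE:
        sc = clean_scenario()
        rec = synthesize_recording(sc)
        _EVENTS_CACHE["res"] = {
            name: compute_event_metrics(rec, sc.protocol, name)
            for name in ("inflation", "deflation", "hematoma")}
    return _EVENTS_CACHE["res"]


class TestEventExtraction:
    def test_inflation_deltas_match_ground_truth(self):
        """Measured per-channel ΔZ equals kernel × gain × 1.2 mL."""
        from bim.simulate import channel_weights
        sc = clean_scenario()
        em = _clean_events()["inflation"]
        expect = sc.focal_gain * 1.2 * channel_weights(sc)
        np.testing.assert_allclose(em.delta_z, expect, atol=1e-8)

    def test_step_deltas_track_volume(self):
        sc = clean_scenario()
        em = _clean_events()["inflation"]
        d = step_deltas(em)[:, sc.inclusion_sector - 1]
        np.testing.assert_allclose(d, sc.focal_gain * em.volumes_ml,
                                   rtol=1e-9)

    def test_di_signs_separate_injury_types(self):
        ev = _clean_events()
        assert ev["inflation"].subject_di() > 0
        assert ev["hematoma"].subject_di() < 0

    def test_pearson_sign_structure(self):
        """Insulative focal r exceeds conductive focal r."""
        ev = _clean_events()
        assert ev["inflation"].mean_pearson_r() > ev["hematoma"].mean_pearson_r()
        # Z is linear in volume while ICP is exponential, so r is high but
        # not exactly 1 at the inclusion channel
        assert ev["inflation"].pearson_r[2] > 0.99
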