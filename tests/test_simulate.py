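"""Forward model: sector kernel, elastance ICP, injury deltas, synthesis."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bim import (
    InjuryScenario,
    ValidationError,
    default_protocol,
    sector_weight,
    simulate_icp,
    simulate_injury_deltas,
    synthesize_carrier_block,
    synthesize_recording,
)
from tests.conftest import clean_scenario


class TestSectorWeight:
    def test_zero_distance_is_one(self):
        assert sector_weight(90.0, 90.0, 30.0) == pytest.approx(1.0)

    def test_symmetry_about_source(self):
        assert sector_weight(45.0, 90.0, 40.0) == pytest.approx(
            sector_weight(135.0, 90.0, 40.0))

    def test_known_value(self):
        # distance 45°, width 45° -> exp(-1/2)
        assert sector_weight(45.0, 0.0, 45.0) == pytest.approx(
            np.exp(-0.5), abs=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(a=st.floats(0, 360), s=st.floats(0, 360))
    def test_wrapped_distance_bounds(self, a, s):
        w = sector_weight(a, s, 45.0)
        assert 0.0 < w <= 1.0
        # wrapping: adding full turns changes nothing
        assert w == pytest.approx(sector_weight(a + 360.0, s, 45.0))

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValidationError):
            sector_weight(0.0, 0.0, 0.0)


class TestIcp:
    def test_no_volume_gives_p0(self):
        proto = default_protocol()
        t = np.linspace(0, 1700, 50)  # inside baseline
        icp = simulate_icp(proto, 10.0, 0.5, t)
        np.testing.assert_allclose(icp, 10.0)

    def test_elastance_closed_form(self):
        """p0=10, E=0.5/mL at V=1.2 mL -> 10·e^0.6 ≈ 18.22 mmHg."""
        proto = default_protocol()
        t_end = proto.phase_window("inflation")[1] - 1.0
        icp = simulate_icp(proto, 10.0, 0.5, [t_end])
        assert icp[0] == pytest.approx(10.0 * np.exp(0.6), rel=1e-9)
        assert icp[0] == pytest.approx(18.22, abs=0.01)

    def test_twelve_inflation_plateaus(self):
        """Stepped volume control shows as discrete plateaus in ICP."""
        proto = default_protocol()
        t0, t1 = proto.phase_window("inflation")
        t = np.arange(t0, t1, 1.0)
        icp = simulate_icp(proto, 10.0, 0.5, t)
        assert len(np.unique(np.round(icp, 9))) == 12
        assert np.all(np.diff(icp) >= 0)

    def test_monotone_in_cumulative_volume(self):
        proto = default_protocol()
        t0, t1 = proto.phase_window("inflation")
        t = np.linspace(0, t1, 500)
        v = proto.balloon_volume(t)
        icp = simulate_icp(proto, 8.0, 0.4, t)
        order = np.argsort(v, kind="stable")
        assert np.all(np.diff(icp[order]) >= -1e-12)

    def test_terminal_drives_icp_to_zero(self):
        proto = default_protocol()
        icp = simulate_icp(proto, 10.0, 0.5, [proto.total_duration_s - 1.0])
        assert icp[0] < 0.1


class TestInjuryDeltas:
    def test_zero_volume_zero_delta(self):
        sc = clean_scenario()
        t = np.linspace(0, 1700, 20)
        np.testing.assert_allclose(simulate_injury_deltas(sc, t), 0.0)

    def test_insulative_peak_at_inclusion(self):
        sc = clean_scenario(contrast_sign=1, inclusion_sector=5)
        t_end = sc.protocol.phase_window("inflation")[1] - 1.0
        dz = simulate_injury_deltas(sc, np.array([t_end]))[:, 0]
        assert int(np.argmax(dz)) + 1 == 5

    def test_conductive_gain_value(self):
        """Conductive focal event, gain 30 Ω/mL at 1.2 mL -> −36 Ω."""
        sc = clean_scenario(contrast_sign=-1, focal_gain=30.0,
                            inclusion_sector=1)
        t_end = sc.protocol.phase_window("inflation")[1] - 1.0
        dz = simulate_injury_deltas(sc, np.array([t_end]))[:, 0]
        assert dz[0] == pytest.approx(-36.0)

    def test_deflation_reverses_inflation(self):
        sc = clean_scenario()
        t_end = sc.protocol.phase_window("deflation")[1] - 1.0
        dz = simulate_injury_deltas(sc, np.array([t_end]))[:, 0]
        np.testing.assert_allclose(dz, 0.0, atol=1e-9)

    def test_hematoma_sign_opposes_balloon(self):
        sc = clean_scenario()
        t_hem = sc.protocol.phase_window("hematoma")[1] - 1.0
        t_inf = sc.protocol.phase_window("inflation")[1] - 1.0
        dz_h = simulate_injury_deltas(sc, np.array([t_hem]))[:, 0]
        dz_i = simulate_injury_deltas(sc, np.array([t_inf]))[:, 0]
        c = sc.inclusion_sector - 1
        assert dz_i[c] > 0 > dz_h[c]

    def test_focal_variance_exceeds_global(self):
        """Across-channel spread is the focal signature."""
        sc = clean_scenario()
        t_inf = sc.protocol.phase_window("inflation")[1] - 1.0
        t_term = sc.protocol.total_duration_s - 1.0
        dz = simulate_injury_deltas(sc, np.array([t_inf, t_term]))
        dz_term = dz[:, 1] - simulate_injury_deltas(
            sc, np.array([sc.protocol.phase_window("global_terminal")[0]]))[:, 0]
        assert np.var(dz[:, 0]) > np.var(dz_term)


class TestSynthesizeRecording:
    def test_noise_free_baseline_equals_baseline_z(self):
        sc = clean_scenario()
        rec = synthesize_recording(sc)
        for tr in rec.traces:
            inside = tr.timestamps < 1700.0
            np.testing.assert_allclose(
                tr.impedance[inside], sc.baseline_z_array()[tr.channel_id - 1])

    def test_determinism(self, default_scenario):
        a = synthesize_recording(default_scenario)
        b = synthesize_recording(default_scenario)
        for ta, tb in zip(a.traces, b.traces):
            np.testing.assert_array_equal(ta.impedance, tb.impedance)
        np.testing.assert_array_equal(a.icp, b.icp)

    def test_baseline_snr_near_84_db(self, default_recording):
        """Default noise gives ≈84 dB per-sample SNR at 1 kΩ baseline."""
        snrs = []
        for tr in default_recording.traces:
            inside = tr.timestamps < 1800.0
            t, z = tr.timestamps[inside], tr.impedance[inside]
            # noise sd from within-slot successive differences, immune to
            # the slow settling drift also present at baseline
            d = np.diff(z)[np.isclose(np.diff(t), np.diff(t).min())]
            sd = float(np.std(d)) / np.sqrt(2.0)
            snrs.append(20.0 * np.log10(np.mean(z) / sd))
        assert np.mean(snrs) == pytest.approx(84.0, abs=1.0)

    def test_sign_separation_invariant(self):
        """Noise-free: ΔZ sign at the nearest channel equals contrast sign."""
        for sign in (+1, -1):
            sc = clean_scenario(contrast_sign=sign)
            rec = synthesize_recording(sc)
            tr = rec.trace(sc.inclusion_sector)
            t_end = sc.protocol.phase_window("inflation")[1]
            base = tr.impedance[tr.timestamps < 1700.0].mean()
            final = tr.impedance[(tr.timestamps > t_end - 80)
                                 & (tr.timestamps < t_end)].mean()
            assert np.sign(final - base) == sign

    def test_sync_events_complete(self, default_recording):
        labels = [e.label for e in default_recording.sync_events]
        assert sum(1 for l in labels if l.startswith("phase:")) == 6
        assert sum(1 for l in labels if l.startswith("step:")) == 30
        assert sum(1 for l in labels if l == "icc") == 30
        assert sum(1 for l in labels if l == "ct") == 30

    def test_one_channel_active_at_a_time(self, clean_recording):
        clean_recording.validate()  # includes the multiplexing invariant


class TestCarrierBlock:
    def test_zero_amplitude_is_pure_noise(self):
        x = synthesize_carrier_block(0.0, 50e3, 250e3, 1000, 0.1, seed=1)
        assert np.abs(np.mean(x)) < 0.05

    def test_quadrature_recovery_exact(self):
        from bim import matched_filter_amplitude
        x = synthesize_carrier_block(1.0, 50e3, 250e3, 5000, 0.0, seed=3)
        a = matched_filter_amplitude(x, 50e3, 250e3)
        assert a == pytest.approx(1.0, abs=1e-9)

    def test_aliasing_configuration_refused(self):
        with pytest.raises(ValidationError, match="alias"):
            synthesize_carrier_block(1.0, 50e3, 50e3, 1000)
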