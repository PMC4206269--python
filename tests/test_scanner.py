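"""Line scheduling, beam field, RF synthesis and the acquisition loop."""

import numpy as np
import pytest

from activeecho import (
    AEDevice,
    Firing,
    GeometryError,
    LinearProbe,
    PlanError,
    Scene,
    ScattererField,
    acquire_frame,
    beam_amplitude,
    line_schedule,
    make_beam_profile,
    preset_probe,
    synthesize_rf_line,
)
from activeecho.injection import FiringPlan, PlanFiring


class TestLineSchedule:
    def test_sixteen_line_spacing(self):
        probe = LinearProbe(
            n_elements=16, pitch=0.3e-3, lines_per_frame=16, tx_aperture=8
        )
        sched = line_schedule(probe)
        assert len(sched) == 16
        xs = np.array([s[1] for s in sched])
        np.testing.assert_allclose(np.diff(xs), 0.3e-3, rtol=1e-12)
        assert sched[0][2] == 0.0

    def test_start_times_arithmetic(self):
        probe = LinearProbe(lines_per_frame=256, line_period=200e-6)
        sched = line_schedule(probe)
        assert sched[-1][2] == pytest.approx(255 * 200e-6)
        assert sched[-1][0] == 255


class TestBeamAmplitude:
    def test_on_axis_equals_peak(self, probe):
        prof = make_beam_profile(probe, 1480.0)
        a = beam_amplitude(probe, prof, 0.0, (0.0, 0.0, 0.03))
        assert a == pytest.approx(prof.peak_amplitude(0.03), rel=1e-12)

    def test_one_sigma_lateral_falloff(self, probe):
        prof = make_beam_profile(probe, 1480.0)
        z = 0.03
        sig = prof.lateral_sigma(z)
        a0 = beam_amplitude(probe, prof, 0.0, (0.0, 0.0, z))
        a1 = beam_amplitude(probe, prof, 0.0, (sig, 0.0, z))
        assert a1 / a0 == pytest.approx(np.exp(-0.5), rel=1e-12)

    def test_elevational_symmetry(self, probe):
        prof = make_beam_profile(probe, 1480.0)
        up = beam_amplitude(probe, prof, 0.0, (0.001, 0.002, 0.03))
        dn = beam_amplitude(probe, prof, 0.0, (0.001, -0.002, 0.03))
        assert up == pytest.approx(dn, rel=1e-12)

    def test_nonpositive_depth_rejected(self, probe):
        prof = make_beam_profile(probe, 1480.0)
        with pytest.raises(GeometryError):
            beam_amplitude(probe, prof, 0.0, (0.0, 0.0, 0.0))

    def test_attenuation_applied(self, probe):
        from activeecho import Layer, Medium

        med = Medium((Layer(None, 1540.0, 0.7),), assumed_c=1540.0)
        prof = make_beam_profile(probe, 1540.0)
        a_free = beam_amplitude(probe, prof, 0.0, (0.0, 0.0, 0.02))
        a_att = beam_amplitude(probe, prof, 0.0, (0.0, 0.0, 0.02), med)
        assert a_att / a_free == pytest.approx(
            10 ** (-0.7 * 2.0 * 10.0 / 20.0), rel=1e-9
        )


class TestBeamProfile:
    def test_focused_waist_at_focus(self, probe):
        prof = make_beam_profile(probe, 1480.0)
        z = np.linspace(0.005, probe.max_depth, 50)
        sig = np.array([prof.lateral_sigma(v) for v in z])
        assert z[np.argmin(sig)] == pytest.approx(probe.focus_depth, abs=1e-3)
        lam = 1480.0 / probe.f0_tx
        assert prof.lateral_sigma(probe.focus_depth) == pytest.approx(
            lam * probe.focus_depth / probe.aperture_width, rel=1e-9
        )

    def test_unfocused_constant_width(self):
        probe = preset_probe("general", focus_depth=None)
        prof = make_beam_profile(probe, 1480.0)
        assert prof.lateral_sigma(0.01) == prof.lateral_sigma(0.04)
        assert prof.lateral_sigma(0.01) == pytest.approx(probe.aperture_width / 4)

    def test_focus_gain_peaks_at_focus(self, probe):
        prof = make_beam_profile(probe, 1480.0)
        assert prof.peak_amplitude(probe.focus_depth) > prof.peak_amplitude(0.01)
        assert prof.peak_amplitude(probe.focus_depth) > prof.peak_amplitude(0.05)


class TestSynthesizeRFLine:
    def test_empty_inputs_zero_line(self, probe, empty_scene):
        line = synthesize_rf_line(probe, empty_scene, 0.0)
        assert np.all(line == 0.0)

    def test_scatterer_echo_at_round_trip_sample(self, probe, water_med):
        z = 0.03
        sc = ScattererField(np.array([[0.0, 0.0, z]]), np.array([1.0]), 0)
        line = synthesize_rf_line(probe, Scene(water_med, sc), 0.0)
        from activeecho import envelope

        peak = np.argmax(envelope(line))
        expected = round(2 * z / water_med.c0 * probe.fs)
        half_pulse = probe.tx_cycles / probe.f0_tx * probe.fs / 2
        assert abs(peak - expected) <= half_pulse

    def test_ae_packet_timing(self, probe, empty_scene):
        from activeecho import envelope

        fire = Firing(fire_time=10e-6, freq=9e6, cycles=8, amplitude=0.5)
        line = synthesize_rf_line(
            probe, empty_scene, 0.0, [fire], ae_position=(0.0, 0.0, 0.03)
        )
        peak = np.argmax(envelope(line))
        expected = (10e-6 + 0.03 / empty_scene.medium.c0) * probe.fs
        assert abs(peak - expected) <= 1.0

    def test_firing_outside_window_rejected(self, probe, empty_scene):
        fire = Firing(fire_time=probe.line_period + 1e-6, freq=9e6, cycles=8, amplitude=0.5)
        with pytest.raises(PlanError):
            synthesize_rf_line(
                probe, empty_scene, 0.0, [fire], ae_position=(0.0, 0.0, 0.03)
            )


class TestAcquireFrame:
    def test_threshold_above_beacon_no_triggers(self, probe, empty_scene):
        dev = AEDevice(position=(0.0, 0.0, 0.04), threshold=1e6)
        frame, log = acquire_frame(probe, empty_scene, dev)
        assert log.count == 0
        assert np.all(frame.samples == 0.0)

    def test_blink_off_phase_fires_nothing(self, probe, speckle_scene):
        dev = AEDevice(
            position=(0.0, 0.0, 0.04),
            blink_enabled=True,
            blink_period=0.5,
            blink_duty=0.5,
        )
        # frame starting at 0.3 s lies wholly in the off phase
        frame_on_gate_off, log = acquire_frame(
            probe, speckle_scene, dev, frame_start=0.3
        )
        frame_no_dev, _ = acquire_frame(probe, speckle_scene, None, frame_start=0.3)
        assert log.count > 0  # triggers are still logged
        np.testing.assert_array_equal(frame_on_gate_off.samples, frame_no_dev.samples)

    def test_latch_one_event_per_line(self, probe, empty_scene):
        dev = AEDevice(position=(0.0, 0.0, 0.04))
        _, log = acquire_frame(probe, empty_scene, dev, rf=False)
        lines = [ev.line_index for ev in log.events]
        assert len(lines) == len(set(lines))
        assert log.count > 0

    def test_superposition_of_device_contribution(self, probe, speckle_scene):
        """frame(scene, on) - frame(scene, off) == frame(empty, same firings):
        the linearity that template acquisition relies on."""
        dev = AEDevice(position=(0.0, 0.0, 0.04))
        on, log = acquire_frame(probe, speckle_scene, dev)
        off, _ = acquire_frame(probe, speckle_scene, dev.at(mode="off"))
        ae_only, _ = acquire_frame(
            probe, Scene(speckle_scene.medium, ScattererField.empty()), dev
        )
        assert log.count > 0
        diff = on.samples - off.samples
        scale = np.abs(ae_only.samples).max()
        np.testing.assert_allclose(diff, ae_only.samples, atol=1e-9 * scale)

    def test_plan_beyond_frame_rejected(self, probe, empty_scene):
        dev = AEDevice(position=(0.0, 0.0, 0.04), mode="pattern")
        plan = FiringPlan((PlanFiring(probe.lines_per_frame, 1e-5),), "sync")
        with pytest.raises(PlanError):
            acquire_frame(probe, empty_scene, dev, plan=plan)

    def test_echo_spot_delayed_by_loop_delay(self, probe, water_med, empty_scene):
        """The AE packet lands loop_delay after the passive round-trip time
        on the element's own line."""
        from activeecho import envelope

        z = 0.04
        dev = AEDevice(position=(0.0, 0.0, z), loop_delay=0.6e-6)
        frame, _ = acquire_frame(probe, empty_scene, dev)
        l = int(np.argmin(np.abs(frame.line_x)))
        peak = np.argmax(envelope(frame.samples[l]))
        t_b = z / water_med.c0
        d = float(np.hypot(frame.line_x[l], z))
        expected = (t_b + 0.6e-6 + d / water_med.c0) * probe.fs
        assert abs(peak - expected) <= 1.0


class TestTriggerCountOrderings:
    def test_aperture_monotonicity_unfocused(self, empty_scene):
        """A larger unfocused transmit aperture delivers more power and
        never lowers the trigger count."""
        counts = []
        for ap in (16, 32, 64):
            probe = preset_probe("general", focus_depth=None, tx_aperture=ap)
            dev = AEDevice(position=(0.0, 0.002, 0.04))
            _, log = acquire_frame(probe, empty_scene, dev, rf=False)
            counts.append(log.count)
        assert counts == sorted(counts)
        assert counts[-1] > counts[0]

    def test_focused_less_gain_sensitive_than_unfocused(self, empty_scene):
        """Trigger-count change per dB of receiver gain is smaller with a
        focused beam (narrower lateral support)."""

        def count_delta(focus):
            probe = preset_probe("general", focus_depth=focus)
            out = []
            for g in (16.0, 25.0):
                dev = AEDevice(position=(0.0, 0.0, 0.04), rx_gain_db=g)
                _, log = acquire_frame(probe, empty_scene, dev, rf=False)
                out.append(log.count)
            return out[1] - out[0]

        assert count_delta(0.04) < count_delta(None)

    def test_count_even_symmetric_in_elevation(self, empty_scene):
        probe = preset_probe("general")
        for e in (1e-3, 3e-3, 5e-3):
            up = acquire_frame(
                probe, empty_scene, AEDevice(position=(0.0, e, 0.04)), rf=False
            )[1].count
            dn = acquire_frame(
                probe, empty_scene, AEDevice(position=(0.0, -e, 0.04)), rf=False
            )[1].count
            assert up == dn


def test_probe_validation():
    with pytest.raises(Exception):
        LinearProbe(fs=20e6, rx_band=(7e6, 13e6))  # fs too low
    with pytest.raises(Exception):
        LinearProbe(tx_aperture=300)
    with pytest.raises(Exception):
        preset_probe("doppler")


def test_mode_presets_band_bookkeeping():
    pen = preset_probe("penetration")
    assert pen.f0_tx == pytest.approx(6.6e6)
    har = preset_probe("harmonic")
    assert har.harmonic and har.f0_tx == pytest.approx(5e6)
    assert har.rx_band == (8.0e6, 12.0e6)
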