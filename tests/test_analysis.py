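"""Template pipeline, SNR/CNR metrics, sweeps and localization."""

import numpy as np
import pytest

from activeecho import (
    AEDevice,
    MetricError,
    NoSignalError,
    RFFrame,
    SweepResult,
    acquire_frame,
    acquire_template,
    compute_snr_cnr,
    detectable_range,
    localize_midplane,
    midplane_sweep,
    parameter_grid,
    preset_probe,
    template_filter,
)


def _frame_from(samples, fs=40e6):
    n_lines = samples.shape[0]
    return RFFrame(
        samples=samples,
        fs=fs,
        line_x=np.arange(n_lines) * 1.5e-4,
        line_period=200e-6,
    )


class TestAcquireTemplate:
    def test_identical_frames_error(self, fast_probe, speckle_scene):
        frame, _ = acquire_frame(fast_probe, speckle_scene, None)
        with pytest.raises(NoSignalError):
            acquire_template(frame, frame)

    def test_support_length_matches_pulse_duration(self, fast_probe, speckle_scene):
        dev = AEDevice(position=(0.0, 0.0, 0.04))
        on, _ = acquire_frame(fast_probe, speckle_scene, dev)
        off, _ = acquire_frame(fast_probe, speckle_scene, dev.at(mode="off"))
        tpl = acquire_template(on, off)
        expected = dev.pulse_cycles / dev.pulse_freq * fast_probe.fs
        assert len(tpl) == pytest.approx(expected, rel=0.5)


class TestTemplateFilter:
    def test_zero_frame_zero_map(self):
        frame = _frame_from(np.zeros((4, 512)))
        m = template_filter(frame, np.array([0.1, -0.2, 0.3]))
        assert np.all(m == 0.0)

    def test_matches_brute_force_sliding_dot(self, rng):
        samples = rng.normal(size=(3, 200))
        tpl = rng.normal(size=17)
        frame = _frame_from(samples)
        m = template_filter(frame, tpl)
        tn = np.linalg.norm(tpl)
        for l in range(3):
            brute = np.array(
                [
                    samples[l, k : k + 17]
                    @ tpl
                    / (tn * np.linalg.norm(samples[l, k : k + 17]))
                    for k in range(200 - 17 + 1)
                ]
            )
            np.testing.assert_allclose(m[l], brute, rtol=1e-9, atol=1e-12)

    def test_exact_instance_scores_unity(self, rng):
        tpl = rng.normal(size=25)
        samples = np.zeros((1, 300))
        samples[0, 140:165] = 3.0 * tpl
        m = template_filter(_frame_from(samples), tpl)
        assert m[0, 140] == pytest.approx(1.0, abs=1e-12)
        assert np.argmax(m[0]) == 140

    def test_argmax_at_injection_point(self, rng):
        from activeecho import gabor

        fs = 40e6
        tpl = gabor(np.arange(-18, 19) / fs, 9e6, 8)
        samples = 0.01 * rng.normal(size=(2, 1024))
        k = 400
        samples[1, k : k + len(tpl)] += tpl
        m = template_filter(_frame_from(samples), tpl)
        line, pos = np.unravel_index(np.argmax(m), m.shape)
        assert line == 1
        assert abs(pos - k) <= 1


class TestComputeSnrCnr:
    def _constructed_pair(self):
        """Checkerboard background (mean 0, std 2) with a +10 uniform spot."""
        off = np.fromfunction(lambda i, j: 2.0 * (-1.0) ** (i + j), (120, 120))
        on = off.copy()
        on[55:60, 55:60] += 10.0
        return on, off

    def test_hand_computed_values(self):
        on, off = self._constructed_pair()
        rep = compute_snr_cnr(on, off, (57, 57), window=50)
        # independent arithmetic: spot = the 25 added pixels; background
        # window mean 0, std 2 exactly
        spot = (on - off) >= 5.0
        bg = off[57 - 25 : 57 + 25, 57 - 25 : 57 + 25]
        snr_hand = (on - off)[spot].mean() / bg.std()
        cnr_hand = abs(on[spot].mean() - bg.mean()) / bg.std()
        assert rep.snr == pytest.approx(snr_hand, abs=1e-9)
        assert rep.cnr == pytest.approx(cnr_hand, abs=1e-9)
        assert rep.snr == pytest.approx(5.0, abs=1e-9)

    def test_cnr_five_for_ten_over_std_two(self):
        on, off = self._constructed_pair()
        rep = compute_snr_cnr(on, off, (57, 57))
        # spot pixels alternate ±2 around +10, mean 10; background mean 0 std 2
        assert rep.cnr == pytest.approx(5.0, abs=0.2)

    def test_identical_frames_error(self):
        img = np.zeros((80, 80))
        with pytest.raises(NoSignalError):
            compute_snr_cnr(img, img, (40, 40))

    def test_window_must_fit(self):
        on, off = self._constructed_pair()
        with pytest.raises(MetricError):
            compute_snr_cnr(on, off, (5, 5), window=50)

    def test_snr_monotone_in_spot_amplitude(self):
        off = np.fromfunction(lambda i, j: 2.0 * (-1.0) ** (i + j), (120, 120))
        snrs = []
        for boost in (5.0, 10.0, 20.0):
            on = off.copy()
            on[55:60, 55:60] += boost
            snrs.append(compute_snr_cnr(on, off, (57, 57)).snr)
        assert snrs == sorted(snrs)
        assert snrs[-1] > snrs[0]


class TestMidplaneSweep:
    def test_noiseless_deterministic(self, probe, empty_scene):
        dev = AEDevice(position=(0.0, 0.0, 0.04))
        offs = np.array([-2e-3, 0.0, 2e-3])
        a = midplane_sweep(probe, empty_scene, dev, offs, repeats=2, seed=0)
        b = midplane_sweep(probe, empty_scene, dev, offs, repeats=2, seed=0)
        np.testing.assert_array_equal(a.trigger_counts, b.trigger_counts)
        # noiseless repeats are identical
        assert np.all(a.trigger_counts[:, 0] == a.trigger_counts[:, 1])

    def test_zero_count_beyond_beam_support(self, probe, empty_scene):
        dev = AEDevice(position=(0.0, 0.0, 0.04))
        sweep = midplane_sweep(
            probe, empty_scene, dev, [25e-3], repeats=1, seed=0
        )
        assert sweep.count_mean[0] == 0


class TestLocalizeMidplane:
    def _gaussian_sweep(self, sigma_mm=3.0, center_mm=0.0, step=0.25):
        offs = np.arange(-9.0, 9.0 + step, step)
        amps = np.exp(-((offs - center_mm) ** 2) / (2 * sigma_mm**2))
        counts = np.rint(40 * amps).astype(int)
        return SweepResult(
            offsets_mm=offs,
            trigger_counts=counts[:, None],
            peak_amplitudes=amps[:, None],
            repeats=1,
        )

    def test_symmetric_sweep_centered_at_zero(self):
        sweep = self._gaussian_sweep()
        est, _ = localize_midplane(sweep, "amplitude")
        assert est == pytest.approx(0.0, abs=1e-9)

    def test_threshold_half_width_closed_form(self):
        # amplitude >= 0.9 max within |e| <= sigma * sqrt(2 ln(1/0.9))
        for sigma in (2.0, 3.0, 4.5):
            sweep = self._gaussian_sweep(sigma_mm=sigma, step=0.1)
            _, hw = localize_midplane(sweep, "amplitude-threshold@0.9")
            assert hw == pytest.approx(0.459 * sigma, rel=0.02)

    def test_recovers_off_center_element(self):
        sweep = self._gaussian_sweep(center_mm=1.4, step=0.2)
        est, _ = localize_midplane(sweep, "amplitude")
        assert abs(est - 1.4) <= 0.2
        # integer counts plateau near the peak: still within the flat top
        est_c, _ = localize_midplane(sweep, "count")
        assert abs(est_c - 1.4) <= 0.5

    def test_flat_sweep_error(self):
        flat = SweepResult(
            offsets_mm=np.arange(5.0),
            trigger_counts=np.full((5, 1), 3),
            peak_amplitudes=np.ones((5, 1)),
            repeats=1,
        )
        with pytest.raises(MetricError):
            localize_midplane(flat, "count")


class TestDetectableRange:
    def _sweep(self, counts, offsets=None):
        counts = np.asarray(counts)
        if offsets is None:
            offsets = np.arange(counts.size) - counts.size // 2
        return SweepResult(
            offsets_mm=np.asarray(offsets, dtype=float),
            trigger_counts=counts[:, None],
            peak_amplitudes=counts[:, None].astype(float),
            repeats=1,
        )

    def test_interpolated_first_zero(self):
        sweep = self._sweep([0, 2, 7, 12, 7, 2, 0], offsets=np.arange(-3, 4))
        assert detectable_range(sweep) == pytest.approx(3.0)

    def test_all_zero_counts(self):
        assert detectable_range(self._sweep([0, 0, 0])) == 0.0

    def test_warns_when_counts_never_reach_zero(self):
        sweep = self._sweep([3, 6, 9, 6, 3], offsets=np.arange(-2, 3))
        with pytest.warns(UserWarning, match="undetermined"):
            assert detectable_range(sweep) == pytest.approx(2.0)

    def test_range_nondecreasing_in_gain(self, probe, empty_scene):
        ranges = []
        for gain in (16.0, 22.0):
            dev = AEDevice(position=(0.0, 0.0, 0.04), rx_gain_db=gain)
            sweep = midplane_sweep(
                probe, empty_scene, dev, np.arange(-12e-3, 12.1e-3, 2e-3),
                repeats=1, seed=0,
            )
            ranges.append(detectable_range(sweep))
        assert ranges[1] >= ranges[0]


class TestParameterGrid:
    def test_zero_power_no_triggers(self, probe, empty_scene):
        dev = AEDevice(position=(0.0, 0.0, 0.04))
        table = parameter_grid(
            probe, empty_scene, dev, {"tx_power": [0.0], "rx_gain_db": [19.0, 30.0]}
        )
        assert (table.trigger_count == 0).all()

    def test_aperture_ordering_unfocused(self, empty_scene):
        probe = preset_probe("general", focus_depth=None)
        dev = AEDevice(position=(0.0, 0.002, 0.04))
        table = parameter_grid(probe, empty_scene, dev, {"tx_aperture": [32, 64]})
        c32 = int(table.loc[table.tx_aperture == 32, "trigger_count"].iloc[0])
        c64 = int(table.loc[table.tx_aperture == 64, "trigger_count"].iloc[0])
        assert c64 >= c32

    def test_saturated_cells_flagged(self, empty_scene):
        probe = preset_probe("general", focus_depth=None)
        dev = AEDevice(position=(0.0, 0.0, 0.04), rx_gain_db=45.0)
        table = parameter_grid(probe, empty_scene, dev, {"rx_gain_db": [45.0]})
        assert int(table.trigger_count.iloc[0]) > 40
        assert bool(table.discarded.iloc[0])
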