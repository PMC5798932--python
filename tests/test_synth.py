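import numpy as np
import pytest

from nmjsignal import Roi, build_train, roi_trace
from nmjsignal import synth


class TestCellTruth:
    def test_all_responders(self):
        cells = synth.make_cell_truth(10, responder_fraction=1.0, seed=0)
        assert sum(c.responder for c in cells) == 10

    def test_half_responders_deterministic(self):
        a = synth.make_cell_truth(10, responder_fraction=0.5, seed=1)
        b = synth.make_cell_truth(10, responder_fraction=0.5, seed=1)
        assert sum(c.responder for c in a) == 5
        assert all(x == y for x, y in zip(a, b))
        nonresp = [c for c in a if not c.responder]
        assert all(c.amplitude == 0.0 for c in nonresp)

    def test_fixed_kinetics_propagate(self):
        cells = synth.make_cell_truth(5, seed=0, onset_latency=1.8,
                                      rise_time=2.86, t50_decay=13.35)
        for c in cells:
            assert c.onset_latency == 1.8
            assert c.rise_time == 2.86
            assert c.t50_decay == 13.35

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            synth.make_cell_truth(5, seed=0, rise_time=(2.0, -1.0))

    def test_invariant_validation(self):
        with pytest.raises(ValueError):
            synth.CellTruth(center=(1, 1), footprint_sigma=1, baseline=60000,
                            amplitude=10000, onset_latency=1, rise_time=1,
                            t50_decay=1, responder=True)


class TestRenderMovie:
    def test_zero_amplitude_gives_constant_movie(self, tonic_train):
        cell = synth.CellTruth(center=(10.0, 10.0), footprint_sigma=2.0,
                               baseline=500.0, amplitude=0.0,
                               onset_latency=1.0, rise_time=1.0,
                               t50_decay=5.0, responder=False)
        movie, _ = synth.render_movie([cell], tonic_train,
                                      frame_shape=(24, 24), n_frames=100)
        assert np.ptp(movie.data, axis=0).max() == 0.0

    def test_noiseless_trace_matches_waveform(self, noiseless_movie,
                                              single_cell, cell_roi,
                                              tonic_train):
        movie, _ = noiseless_movie
        trace = roi_trace(movie, cell_roi)
        t = movie.times
        yy, xx = np.mgrid[0:48, 0:64]
        fp = np.exp(-((xx - 32.0) ** 2 + (yy - 24.0) ** 2) / (2 * 3.0**2))
        fp_mean = fp[cell_roi.slices()].mean()
        w = synth.transient_waveform(t, 2.0, 3.0, 12.0, tonic_train)
        expected = (200.0 + single_cell.baseline * fp
                    )[cell_roi.slices()].mean() + 2000.0 * fp_mean * w
        assert np.max(np.abs(trace.values - expected)) <= 0.5  # quantization

    def test_noiseless_peak_within_one_frame(self, noiseless_movie, cell_roi):
        movie, _ = noiseless_movie
        trace = roi_trace(movie, cell_roi)
        peak_t = trace.time[np.argmax(trace.values)]
        assert abs(peak_t - (5.0 + 2.0 + 3.0)) <= 1.0 / movie.frame_rate

    def test_bit_identical_under_seed(self, tonic_train):
        cells = synth.make_cell_truth(3, seed=5, frame_shape=(24, 32))
        noise = synth.NoiseModel(read_noise_sd=20.0, shot_noise=True,
                                 jitter_max=2, seed=9)
        m1, r1 = synth.render_movie(cells, tonic_train, frame_shape=(24, 32),
                                    n_frames=60, noise=noise)
        m2, r2 = synth.render_movie(cells, tonic_train, frame_shape=(24, 32),
                                    n_frames=60, noise=noise)
        np.testing.assert_array_equal(m1.data, m2.data)
        np.testing.assert_array_equal(r1["jitter"], r2["jitter"])

    def test_phasic_off_gain_modulates_waveform(self, phasic_train):
        t = np.arange(0, 60, 0.04)
        w_mod = synth.transient_waveform(t, 1.0, 2.0, 10.0, phasic_train,
                                         off_gain=0.3)
        w_full = synth.transient_waveform(t, 1.0, 2.0, 10.0, phasic_train,
                                          off_gain=1.0)
        off = phasic_train.is_on(t) == False  # noqa: E712
        in_epoch = (t >= phasic_train.onset) & (t < phasic_train.end)
        sel = off & in_epoch & (w_full > 0)
        np.testing.assert_allclose(w_mod[sel], 0.3 * w_full[sel], rtol=1e-12)
        np.testing.assert_allclose(w_mod[~in_epoch], w_full[~in_epoch])


class TestContractionVideo:
    def test_static_truth_constant_separation(self):
        truth = synth.ContractionTruth(peak_shortening=0.0)
        _, out = synth.render_contraction_video(truth, n_frames=50)
        sep = np.linalg.norm(out.landmarks[:, 0] - out.landmarks[:, 1],
                             axis=1)
        np.testing.assert_allclose(sep, sep[0], atol=1e-9)

    def test_peak_separation_arithmetic(self):
        truth = synth.ContractionTruth(rest_distance=4000.0,
                                       peak_shortening=750.0)
        _, out = synth.render_contraction_video(truth, n_frames=400,
                                                pixel_scale=10.0)
        sep_px = np.linalg.norm(out.landmarks[:, 0] - out.landmarks[:, 1],
                                axis=1)
        assert abs(sep_px.min() - (400.0 - 75.0)) < 0.05

    def test_ending_fraction_at_stim_end(self):
        truth = synth.ContractionTruth(rest_distance=3000.0,
                                       peak_shortening=600.0,
                                       ending_fraction=0.6,
                                       stim_onset=1.0, stim_duration=10.0)
        video, out = synth.render_contraction_video(truth, n_frames=300)
        f_end = int(11.0 * video.frame_rate) - 1  # last stimulated frame
        sep_um = np.linalg.norm(out.landmarks[f_end, 0]
                                - out.landmarks[f_end, 1]) * 10.0
        assert abs(sep_um - (3000.0 - 0.6 * 600.0)) < 2.0

    def test_overlapping_landmarks_rejected(self):
        truth = synth.ContractionTruth(rest_distance=100.0,
                                       peak_shortening=90.0)
        with pytest.raises(ValueError):
            synth.render_contraction_video(truth, n_frames=50,
                                           pixel_scale=10.0)


class TestSimulateSweeps:
    def test_flat_trace_without_events(self):
        sweep, _ = synth.simulate_sweeps(None, duration=1.0, rmp=-70.0)
        np.testing.assert_allclose(sweep.vm, -70.0)

    def test_first_failed_ap_time(self):
        train = build_train(40.0, 1.0, 45.0)
        sweep, rec = synth.simulate_sweeps(train, duration=47.0,
                                           failure_start_index=600, seed=0)
        flags = rec["success"]
        assert flags[:600].all() and not flags[600:].any()
        first_failed = train.pulse_times[600]
        assert first_failed == pytest.approx(1.0 + 15.0)

    def test_mepp_count_in_poisson_interval(self):
        sweep, rec = synth.simulate_sweeps(None, duration=100.0,
                                           mepp_rate=0.4, seed=11)
        n = len(rec["mepp_times"])
        # 95% interval of Poisson(40)
        assert 28 <= n <= 53

    def test_deterministic_under_seed(self):
        train = build_train(40.0, 0.5, 2.0)
        s1, _ = synth.simulate_sweeps(train, duration=3.0, mepp_rate=1.0,
                                      noise_sd_mv=0.3, seed=21)
        s2, _ = synth.simulate_sweeps(train, duration=3.0, mepp_rate=1.0,
                                      noise_sd_mv=0.3, seed=21)
        np.testing.assert_array_equal(s1.vm, s2.vm)

    def test_out_of_range_amplitude_rejected(self):
        with pytest.raises(ValueError):
            synth.simulate_sweeps(None, duration=1.0, rmp=-20.0,
                                  event_params={"ap": {"amplitude": 100.0,
                                                       "rise_ms": 1.0,
                                                       "t50_ms": 2.0}})
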