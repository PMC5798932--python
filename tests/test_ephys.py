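import numpy as np
import pytest

from nmjsignal import (
    IonConditions,
    SweepSet,
    ap_success,
    build_train,
    detect_events,
    event_metrics,
    failure_time,
    ghk_potential,
    mepp_stats,
    rmp_filter,
    rundown,
)
from nmjsignal.ephys import DetectionError, EventMetrics
from nmjsignal import synth


def brute_force_failure(flags, stim_times, window=8):
    """Independent scan: first trailing window below half success, then the
    earliest failed stimulus inside that window."""
    flags = list(flags)
    for i in range(window - 1, len(flags)):
        win = flags[i - window + 1:i + 1]
        if sum(win) / window < 0.5:
            for j, ok in enumerate(win):
                if not ok:
                    return float(stim_times[i - window + 1 + j])
    return None


class TestEventMetrics:
    def test_epp_amplitude_recovered(self):
        train = build_train(1.0, 0.5, 3.0)
        sweep, _ = synth.simulate_sweeps(
            train, duration=4.0, noise_sd_mv=0.1, seed=0,
            event_params={"ap": {"amplitude": 24.0, "rise_ms": 3.76,
                                 "t50_ms": 5.83}})
        m = event_metrics(sweep, float(train.pulse_times[0]))
        assert m.amplitude == pytest.approx(24.0, abs=0.5)
        assert m.rise_to_peak == pytest.approx(3.76, abs=0.5)
        assert m.t50_decay == pytest.approx(5.83, abs=0.6)

    def test_symmetric_triangle_t50_is_half_fall(self):
        rate = 10000.0
        t = np.arange(int(0.2 * rate)) / rate
        vm = np.full_like(t, -70.0)
        up = (t >= 0.05) & (t < 0.06)
        vm[up] = -70.0 + 20.0 * (t[up] - 0.05) / 0.01
        down = (t >= 0.06) & (t < 0.07)
        vm[down] = -50.0 - 20.0 * (t[down] - 0.06) / 0.01
        sweep = SweepSet(time=t, vm=vm, sample_rate=rate)
        m = event_metrics(sweep, 0.05, search_window_ms=25.0)
        assert m.amplitude == pytest.approx(20.0, abs=0.1)
        assert m.t50_decay == pytest.approx(5.0, abs=0.2)  # half of 10 ms fall

    def test_flat_sweep_raises(self):
        t = np.arange(1000) / 10000.0
        sweep = SweepSet(time=t, vm=np.full_like(t, -70.0), sample_rate=10000.0)
        with pytest.raises(DetectionError):
            event_metrics(sweep, 0.05)


class TestMeppStats:
    def test_four_events_in_ten_seconds(self):
        out = mepp_stats(_flat_sweep(), [1.0, 3.0, 5.0, 9.0], (0.0, 10.0))
        assert out["frequency_per_s"] == pytest.approx(0.4)

    def test_empty_event_list(self):
        out = mepp_stats(_flat_sweep(), [], (0.0, 10.0))
        assert out["frequency_per_s"] == 0.0

    def test_poisson_rate_recovered(self):
        sweep, rec = synth.simulate_sweeps(None, duration=100.0,
                                           mepp_rate=0.4, noise_sd_mv=0.1,
                                           seed=13)
        times = detect_events(sweep, threshold_mv=1.0)
        out = mepp_stats(sweep, list(times), (0.0, 100.0))
        assert 0.28 <= out["frequency_per_s"] <= 0.53  # Poisson(40) 95% band

    def test_amplitude_summary_from_event_metrics(self):
        evts = [EventMetrics(1.0, 2.4, 3.7, 5.8, "mEPP"),
                EventMetrics(2.0, 2.6, 3.7, 5.8, "mEPP")]
        out = mepp_stats(_flat_sweep(), evts, (0.0, 10.0))
        assert out["amplitude_mean_mv"] == pytest.approx(2.5)

    def test_zero_length_epoch_rejected(self):
        with pytest.raises(ValueError):
            mepp_stats(_flat_sweep(), [], (1.0, 1.0))


def _flat_sweep():
    t = np.arange(int(10 * 1000.0)) / 1000.0
    return SweepSet(time=t, vm=np.full_like(t, -70.0), sample_rate=1000.0)


class TestApSuccess:
    def test_all_aps_successful(self):
        train = build_train(40.0, 0.5, 1.0)
        sweep, _ = synth.simulate_sweeps(train, duration=2.0, seed=0)
        assert ap_success(sweep).all()

    def test_subthreshold_epps_fail(self):
        train = build_train(40.0, 0.5, 1.0)
        sweep, _ = synth.simulate_sweeps(
            train, duration=2.0, seed=0, failure_start_index=0,
            failure_mode="subthreshold")
        assert not ap_success(sweep).any()

    def test_programmed_failure_flips_at_index(self):
        train = build_train(40.0, 1.0, 45.0)
        sweep, _ = synth.simulate_sweeps(train, duration=47.0,
                                         failure_start_index=600,
                                         noise_sd_mv=0.5, seed=2)
        flags = ap_success(sweep)
        assert flags[:600].all()
        assert not flags[600:].any()

    def test_overlapping_windows_rejected(self):
        train = build_train(200.0, 0.5, 1.0)
        sweep, _ = synth.simulate_sweeps(train, duration=2.0, seed=0)
        with pytest.raises(ValueError):
            ap_success(sweep, response_window_ms=10.0)


class TestFailureTime:
    def test_all_successes_no_failure(self):
        times = np.arange(100) / 40.0
        assert failure_time(np.ones(100, bool), times) is None

    def test_alternating_is_exactly_half_never_below(self):
        flags = np.tile([True, False], 50)
        times = np.arange(100) / 40.0
        assert failure_time(flags, times) is None

    def test_programmed_failure_localized_exactly(self):
        flags = np.ones(1800, bool)
        flags[600:] = False
        times = 1.0 + np.arange(1800) / 40.0
        assert failure_time(flags, times) == pytest.approx(1.0 + 15.0)

    def test_matches_brute_force_on_random_sequences(self):
        rng = np.random.default_rng(17)
        for _ in range(1000):
            n = int(rng.integers(8, 60))
            flags = rng.random(n) < rng.uniform(0.2, 0.9)
            times = np.sort(rng.uniform(0, 45, n))
            assert failure_time(flags, times) == \
                brute_force_failure(flags, times)

    def test_empty_flags_rejected(self):
        with pytest.raises(ValueError):
            failure_time([], [])


class TestRundown:
    def test_constant_amplitudes_100_percent(self):
        assert rundown(np.full(20, 24.0), 17) == pytest.approx(100.0)

    def test_one_third_final(self):
        amps = np.concatenate([np.full(3, 24.0), np.full(3, 8.0)])
        assert rundown(amps, 3) == pytest.approx(100.0 / 3.0)

    def test_scale_invariant(self):
        rng = np.random.default_rng(3)
        amps = rng.uniform(5, 25, 30)
        assert rundown(amps, 20) == pytest.approx(rundown(5 * amps, 20))

    def test_exponential_rundown_to_34_percent(self):
        n = 1800
        amps = 24.0 * np.exp(np.log(0.34) * np.arange(n) / (n - 2))
        assert rundown(amps, n - 3) == pytest.approx(34.0, rel=0.02)

    def test_too_few_potentials_rejected(self):
        with pytest.raises(ValueError):
            rundown([24.0, 23.0], 0)


class TestRmpFilter:
    def _sweep(self, rmp):
        t = np.arange(100) / 1000.0
        return SweepSet(time=t, vm=np.full_like(t, rmp), sample_rate=1000.0)

    def test_paper_scale_rmp_included(self):
        kept = rmp_filter([self._sweep(-68.5)])
        assert len(kept) == 1

    def test_depolarized_fiber_excluded(self):
        assert rmp_filter([self._sweep(-50.0)]) == []

    def test_closed_boundaries(self):
        kept = rmp_filter([self._sweep(-60.0), self._sweep(-75.0),
                           self._sweep(-59.9), self._sweep(-75.1)])
        assert len(kept) == 2


class TestGhk:
    def test_symmetric_potassium_zero(self):
        ions = IonConditions(k_out=100.0, k_in=100.0)
        assert ghk_potential(ions) == pytest.approx(0.0, abs=1e-12)

    def test_doubling_k_out_shift(self):
        shift = ghk_potential(IonConditions(k_out=10.0)) \
            - ghk_potential(IonConditions(k_out=5.0))
        assert shift == pytest.approx(26.71 * np.log(2), abs=0.05)

    def test_potassium_nernst_value(self):
        vm = ghk_potential(IonConditions(k_out=5.0, k_in=140.0))
        assert vm == pytest.approx(-89.0, abs=0.5)

    def test_reduces_to_nernst_single_ion(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            co, ci = rng.uniform(1, 200, 2)
            T = rng.uniform(273, 320)
            ions = IonConditions(temperature=T, k_out=co, k_in=ci,
                                 p_k=rng.uniform(0.1, 5.0))
            nernst = 1000.0 * (8.314462618 / 96485.33212) * T * np.log(co / ci)
            assert abs(ghk_potential(ions) - nernst) <= 1e-12 * max(abs(nernst), 1.0)

    def test_strictly_increasing_in_k_out(self):
        vals = [ghk_potential(IonConditions(k_out=k, p_na=0.04, p_cl=0.45))
                for k in np.linspace(2, 20, 10)]
        assert (np.diff(vals) > 0).all()

    def test_all_zero_permeabilities_rejected(self):
        with pytest.raises(ValueError):
            IonConditions(p_k=0.0, p_na=0.0, p_cl=0.0)
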