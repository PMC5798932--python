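"""Electrophysiological metrics for intracellular muscle recordings.

Per-event measures (amplitude above local baseline, rise to peak, time to
50% decay), miniature endplate potential (mEPP) frequency, per-stimulus
muscle action potential success, the neural-transmission failure time (the
first point at which fewer than half of the nerve stimuli in a trailing
window are transduced into successful muscle APs), transmitter-release
rundown (three-potential averages as a percent of the first three), the
resting-membrane-potential inclusion filter (-75..-60 mV, closed interval),
and the Goldman-Hodgkin-Katz voltage equation, which reduces to the Nernst
potential when only one ion is permeant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "SweepSet",
    "EventMetrics",
    "IonConditions",
    "event_metrics",
    "detect_events",
    "mepp_stats",
    "ap_success",
    "failure_time",
    "rundown",
    "rmp_filter",
    "ghk_potential",
]

#: Gas constant / Faraday constant, volts per kelvin.
_R_OVER_F = 8.314462618 / 96485.33212


@dataclass
class SweepSet:
    """A voltage sweep with stimulus times and resting potential.

    ``vm`` in mV sampled at ``sample_rate`` Hz; ``stim_times`` sorted
    stimulus times in seconds; ``rmp`` the mean pre-stimulus membrane
    potential (computed from the samples before the first stimulus when not
    given).
    """

    time: np.ndarray
    vm: np.ndarray
    sample_rate: float
    stim_times: np.ndarray = field(default_factory=lambda: np.array([]))
    rmp: float | None = None
    cell_label: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.vm = np.asarray(self.vm, dtype=float)
        self.stim_times = np.asarray(self.stim_times, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if len(self.stim_times) and np.any(np.diff(self.stim_times) < 0):
            raise ValueError("stim_times must be sorted ascending")
        if self.rmp is None:
            if len(self.stim_times):
                pre = self.time < self.stim_times[0] - 2e-3
                self.rmp = float(self.vm[pre].mean()) if pre.any() \
                    else float(self.vm[0])
            else:
                self.rmp = float(self.vm.mean())

    def index(self, t: float) -> int:
        return int(round(t * self.sample_rate))


@dataclass
class EventMetrics:
    """One detected synaptic or action-potential event."""

    event_time: float
    amplitude: float
    rise_to_peak: float  # ms
    t50_decay: float | None  # ms, None if censored
    event_class: str = ""


class DetectionError(RuntimeError):
    """Raised when an expected event cannot be found in a sweep."""


def event_metrics(
    sweep: SweepSet,
    event_time: float,
    baseline_window_ms: float = 5.0,
    search_window_ms: float = 20.0,
    event_class: str = "",
) -> EventMetrics:
    """Amplitude and kinetics of a single event at a known time.

    The local baseline is the mean over ``baseline_window_ms`` before the
    event; onset is the first departure above 2 x baseline SD sustained for
    2 samples; amplitude is peak minus baseline; rise to peak runs from
    onset to the peak; t50 decay from the peak to the first interpolated
    crossing of baseline + amplitude/2.
    """
    i_evt = sweep.index(event_time)
    n_base = max(int(baseline_window_ms / 1000.0 * sweep.sample_rate), 2)
    i0 = max(i_evt - n_base, 0)
    if i0 == i_evt:
        raise ValueError("event too close to the start for a baseline window")
    base = sweep.vm[i0:i_evt]
    b_mean = float(base.mean())
    b_sd = float(base.std(ddof=0))
    thr = b_mean + 2.0 * max(b_sd, 1e-9)

    n_search = int(search_window_ms / 1000.0 * sweep.sample_rate)
    i1 = min(i_evt + n_search, len(sweep.vm))
    seg = sweep.vm[i_evt:i1]
    if len(seg) < 3:
        raise DetectionError("search window extends past the sweep")
    i_pk = i_evt + int(np.argmax(seg))
    amp = float(sweep.vm[i_pk] - b_mean)
    if amp <= 2.0 * max(b_sd, 1e-9):
        raise DetectionError(
            f"no event found at t={event_time:.4f} s (peak {amp:.3f} mV "
            "above baseline)"
        )

    above = sweep.vm[i_evt:i_pk + 1] > thr
    onset_rel = None
    run = 0
    for i, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= 2:
            onset_rel = i - 1
            break
    if onset_rel is None:
        onset_rel = int(np.argmax(above)) if above.any() else 0
    i_on = i_evt + onset_rel
    rise_ms = (i_pk - i_on) / sweep.sample_rate * 1000.0

    half = b_mean + amp / 2.0
    t50_ms = None
    post = sweep.vm[i_pk:i1]
    below = post <= half
    if below.any():
        j = int(np.argmax(below))
        if j > 0:
            v0, v1 = post[j - 1], post[j]
            frac = (v0 - half) / (v0 - v1) if v0 != v1 else 0.0
            t50_ms = (j - 1 + frac) / sweep.sample_rate * 1000.0
        else:
            t50_ms = 0.0
    return EventMetrics(event_time=float(event_time), amplitude=amp,
                        rise_to_peak=rise_ms, t50_decay=t50_ms,
                        event_class=event_class)


def detect_events(
    sweep: SweepSet,
    threshold_mv: float = 1.0,
    min_interval_ms: float = 10.0,
) -> np.ndarray:
    """Times of spontaneous depolarizing events (simple prominence picker).

    Intended for mEPP counting in quiescent epochs; returns peak times in
    seconds.
    """
    distance = max(int(min_interval_ms / 1000.0 * sweep.sample_rate), 1)
    peaks, _ = find_peaks(sweep.vm, prominence=threshold_mv,
                          distance=distance)
    return sweep.time[peaks]


def mepp_stats(sweep: SweepSet, detected_events: list,
               epoch: tuple[float, float]) -> dict:
    """mEPP frequency (events/s) and amplitude summary over an epoch.

    ``detected_events`` may be event times (s) or :class:`EventMetrics`.
    """
    start, end = epoch
    if end <= start:
        raise ValueError("epoch must have positive duration")
    times = np.array([
        e.event_time if isinstance(e, EventMetrics) else float(e)
        for e in detected_events
    ])
    sel = (times >= start) & (times < end)
    freq = float(sel.sum()) / (end - start)
    amps = np.array([e.amplitude for e in detected_events
                     if isinstance(e, EventMetrics)])
    out = {"frequency_per_s": freq, "n_events": int(sel.sum())}
    if len(amps):
        out["amplitude_mean_mv"] = float(amps.mean())
        out["amplitude_sd_mv"] = float(amps.std(ddof=0))
    return out


def ap_success(
    sweep: SweepSet,
    stim_times: np.ndarray | None = None,
    criterion_mv: float = 40.0,
    response_window_ms: float = 10.0,
) -> np.ndarray:
    """Per-stimulus success flags for muscle action potentials.

    A stimulus is successful iff Vm exceeds ``RMP + criterion_mv`` within
    ``response_window_ms`` after it.  Windows must not overlap the next
    stimulus.
    """
    if stim_times is None:
        stim_times = sweep.stim_times
    stim_times = np.asarray(stim_times, dtype=float)
    if len(stim_times) > 1:
        isi = np.min(np.diff(stim_times))
        if response_window_ms / 1000.0 > isi + 1e-12:
            raise ValueError(
                f"response window {response_window_ms} ms overlaps the next "
                f"stimulus (ISI {isi * 1000:.1f} ms)"
            )
    level = sweep.rmp + criterion_mv
    n_win = max(int(response_window_ms / 1000.0 * sweep.sample_rate), 1)
    flags = np.zeros(len(stim_times), dtype=bool)
    for i, ts in enumerate(stim_times):
        i0 = sweep.index(ts)
        seg = sweep.vm[i0:i0 + n_win + 1]
        flags[i] = len(seg) > 0 and float(seg.max()) >= level
    return flags


def failure_time(
    success_flags: np.ndarray,
    stim_times: np.ndarray,
    window: int = 8,
) -> float | None:
    """Time of neural-transmission failure, or None if it never occurs.

    Failure is declared at the first stimulus whose trailing window of
    ``window`` stimuli contains fewer than half successes; the reported time
    is that of the earliest failed stimulus inside that triggering window,
    which localizes a programmed failure onset exactly.
    """
    flags = np.asarray(success_flags, dtype=bool)
    stim_times = np.asarray(stim_times, dtype=float)
    if len(flags) == 0:
        raise ValueError("empty success-flag list")
    if window < 2:
        raise ValueError("window must be >= 2")
    if len(flags) != len(stim_times):
        raise ValueError("flags and stim_times must have equal length")
    if len(flags) < window:
        return None
    frac = np.convolve(flags.astype(float), np.ones(window), mode="valid") \
        / window
    trig = np.flatnonzero(frac < 0.5)
    if len(trig) == 0:
        return None
    i_end = int(trig[0]) + window - 1  # last stimulus of the window
    i_start = i_end - window + 1
    failed = np.flatnonzero(~flags[i_start:i_end + 1])
    return float(stim_times[i_start + int(failed[0])])


def rundown(potential_amplitudes: np.ndarray, at_index: int) -> float:
    """Amplitude rundown as a percent of the initial responses.

    The mean of three potentials at ``at_index`` is expressed as a percent
    of the mean of the first three potentials.
    """
    amps = np.asarray(potential_amplitudes, dtype=float)
    if len(amps) < 3:
        raise ValueError("need at least 3 initial potentials")
    if at_index + 3 > len(amps):
        raise ValueError("fewer than 3 potentials at the requested index")
    return 100.0 * float(amps[at_index:at_index + 3].mean()) \
        / float(amps[:3].mean())


def rmp_filter(sweeps: list[SweepSet], low: float = -75.0,
               high: float = -60.0) -> list[SweepSet]:
    """Keep sweeps whose resting membrane potential lies in [low, high] mV.

    The interval is closed at both ends (a fiber at exactly -60 mV is
    included).
    """
    if low >= high:
        raise ValueError("low bound must be below high bound (signed mV)")
    return [s for s in sweeps if low <= s.rmp <= high]


@dataclass(frozen=True)
class IonConditions:
    """Ion concentrations (mM) and relative permeabilities for the GHK
    voltage equation.  Temperature in kelvin."""

    temperature: float = 310.0
    k_out: float = 5.0
    k_in: float = 140.0
    na_out: float = 145.0
    na_in: float = 12.0
    cl_out: float = 120.0
    cl_in: float = 30.0
    p_k: float = 1.0
    p_na: float = 0.0
    p_cl: float = 0.0

    def __post_init__(self) -> None:
        conc = (self.k_out, self.k_in, self.na_out, self.na_in,
                self.cl_out, self.cl_in)
        if any(c <= 0 for c in conc):
            raise ValueError("concentrations must be positive")
        perms = (self.p_k, self.p_na, self.p_cl)
        if any(p < 0 for p in perms):
            raise ValueError("permeabilities must be >= 0")
        if all(p == 0 for p in perms):
            raise ValueError("at least one permeability must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")


def ghk_potential(ions: IonConditions) -> float:
    """Goldman-Hodgkin-Katz membrane potential in mV.

    Vm = (RT/F) ln[(P_K[K]o + P_Na[Na]o + P_Cl[Cl]i) /
                   (P_K[K]i + P_Na[Na]i + P_Cl[Cl]o)].
    With a single permeant cation this is the Nernst potential.
    """
    num = ions.p_k * ions.k_out + ions.p_na * ions.na_out \
        + ions.p_cl * ions.cl_in
    den = ions.p_k * ions.k_in + ions.p_na * ions.na_in \
        + ions.p_cl * ions.cl_out
    if num <= 0 or den <= 0:
        raise ValueError("GHK numerator/denominator must be positive")
    return 1000.0 * _R_OVER_F * ions.temperature * float(np.log(num / den))
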