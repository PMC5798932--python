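"""Ground-truthed synthetic data generators.

Every downstream stage of the pipeline is testable without recordings: this
module renders (i) 16-bit fluorescence movies of perisynaptic Schwann cell
somata as Gaussian blobs whose brightness follows a stimulus-locked
transient, (ii) brightfield contraction videos of two trackable landmarks
whose separation follows a contraction-fatigue curve, and (iii) intracellular
voltage sweeps containing mEPPs, EPPs and muscle action potentials with a
programmable transmission-failure onset.

Default parameter scales are the measured population values for the neonatal
mouse diaphragm preparation: transient onset latency 1.8 +/- 0.74 s after
stimulus onset, rise to peak 2.86 +/- 0.49 s, time to 50% decay
13.35 +/- 4.22 s; basal EPP amplitude 24 mV; muscle AP amplitude 67.7 mV
(rise 1.16 ms, half-decay 2.42 ms); mEPPs of 2.52 mV at 0.38 events/s;
resting membrane potential -68.5 mV; peak shortening 751.6 um with an ending
length change of 72.6% of peak.

The transient waveform template is the simplest curve with exactly the three
measured degrees of freedom: zero until the onset latency, a linear rise
over the rise time, then exponential decay at rate ln(2)/t50.  During the
off-periods of a phasic train the waveform is scaled by a configurable
off-gain (default 0.3), producing the partial per-cycle dropoff seen in
phasic recordings without returning fully to baseline.  All generators are
bit-identical under a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .stim import StimulusTrain
from .preprocess import Movie

__all__ = [
    "CellTruth",
    "NoiseModel",
    "ContractionTruth",
    "PAPER_KINETICS",
    "make_cell_truth",
    "transient_waveform",
    "render_movie",
    "render_contraction_video",
    "simulate_sweeps",
]

#: Population kinetics of activity-evoked TPSC transients (mean, sd), seconds.
PAPER_KINETICS = {
    "onset_latency": (1.8, 0.74),
    "rise_time": (2.86, 0.49),
    "t50_decay": (13.35, 4.22),
}


@dataclass
class CellTruth:
    """Ground truth for one synthetic cell.

    ``center`` is (x, y) in 0-based pixels; ``footprint_sigma`` the isotropic
    Gaussian footprint width; ``baseline``/``amplitude`` the resting and peak
    added brightness in iu16; kinetics are in seconds.  Non-responders carry
    amplitude 0.
    """

    center: tuple[float, float]
    footprint_sigma: float
    baseline: float
    amplitude: float
    onset_latency: float
    rise_time: float
    t50_decay: float
    responder: bool
    label: str = ""

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.onset_latency < 0:
            raise ValueError("onset_latency must be >= 0")
        if self.rise_time <= 0 or self.t50_decay <= 0:
            raise ValueError("rise_time and t50_decay must be positive")
        if self.baseline + self.amplitude > 65535:
            raise ValueError("baseline + amplitude exceeds the 16-bit range")


@dataclass
class NoiseModel:
    """Camera and preparation noise for synthetic movies.

    ``read_noise_sd`` Gaussian read noise (iu16); ``shot_noise`` Poisson
    noise on the expected intensity; ``drift_amplitude`` a linear additive
    background ramp over the recording (iu16); ``jitter_max`` maximal rigid
    per-frame translation (pixels).  Identical seeds give bit-identical
    output.
    """

    read_noise_sd: float = 0.0
    shot_noise: bool = False
    drift_amplitude: float = 0.0
    jitter_max: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_noise_sd < 0 or self.drift_amplitude < 0 or self.jitter_max < 0:
            raise ValueError("noise parameters must be non-negative")


@dataclass
class ContractionTruth:
    """Ground truth for a synthetic contraction video.

    Distances in microns; ``ending_fraction`` is the ending shortening as a
    fraction of peak shortening.  ``landmarks`` (set by the renderer) holds
    per-frame (x, y) positions of both landmarks, shape (n_frames, 2, 2).
    """

    rest_distance: float = 4000.0
    peak_shortening: float = 751.6
    time_to_peak: float = 4.0
    ending_fraction: float = 0.726
    stim_onset: float = 2.0
    stim_duration: float = 45.0
    landmarks: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not (0.0 <= self.ending_fraction <= 1.0):
            raise ValueError("ending_fraction must lie in [0, 1]")
        if self.peak_shortening < 0:
            raise ValueError("peak_shortening must be >= 0")

    def distance_series(self, times: np.ndarray) -> np.ndarray:
        """Landmark separation (um) at the given times."""
        return self.rest_distance - self.shortening_series(times)

    def shortening_series(self, times: np.ndarray) -> np.ndarray:
        """Shortening (um, positive) at the given times: linear rise to the
        peak, linear fatigue decline to ending_fraction x peak at the end of
        the stimulation epoch, then linear relaxation back to rest."""
        t = np.asarray(times, dtype=float)
        s = np.zeros_like(t)
        t_pk = self.stim_onset + self.time_to_peak
        t_end = self.stim_onset + self.stim_duration
        rising = (t >= self.stim_onset) & (t < t_pk)
        s[rising] = self.peak_shortening * (t[rising] - self.stim_onset) / self.time_to_peak
        fatiguing = (t >= t_pk) & (t < t_end)
        end_level = self.ending_fraction * self.peak_shortening
        if t_end > t_pk:
            frac = (t[fatiguing] - t_pk) / (t_end - t_pk)
            s[fatiguing] = self.peak_shortening + frac * (end_level - self.peak_shortening)
        relax_tau = 2.0  # s, post-stimulus relaxation
        after = t >= t_end
        s[after] = end_level * np.exp(-(t[after] - t_end) / relax_tau)
        return s


def _draw(rng: np.random.Generator, spec, floor: float | None = None,
          n: int = 1) -> np.ndarray:
    """Draw n values from a fixed value or a (mean, sd) pair."""
    if np.isscalar(spec):
        vals = np.full(n, float(spec))
    else:
        mean, sd = spec
        if sd < 0:
            raise ValueError(f"negative sd in parameter spec {spec!r}")
        vals = rng.normal(mean, sd, size=n)
    if floor is not None:
        vals = np.maximum(vals, floor)
    return vals


def make_cell_truth(
    n_cells: int,
    responder_fraction: float = 1.0,
    seed: int = 0,
    frame_shape: tuple[int, int] = (96, 128),
    margin: int = 10,
    onset_latency=PAPER_KINETICS["onset_latency"],
    rise_time=PAPER_KINETICS["rise_time"],
    t50_decay=PAPER_KINETICS["t50_decay"],
    baseline=(1200.0, 150.0),
    amplitude=(2500.0, 400.0),
    footprint_sigma=2.5,
) -> list[CellTruth]:
    """Draw ground-truth cells with population-scale kinetics.

    Exactly ``round(n_cells * responder_fraction)`` cells are flagged
    responders; the rest get amplitude 0.  Parameter specs may be a fixed
    value or a (mean, sd) pair; draws are independent across fields and
    deterministic given ``seed``.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if not (0.0 <= responder_fraction <= 1.0):
        raise ValueError("responder_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    h, w = frame_shape
    xs = rng.uniform(margin, w - margin, size=n_cells)
    ys = rng.uniform(margin, h - margin, size=n_cells)
    lat = _draw(rng, onset_latency, floor=0.0, n=n_cells)
    rise = _draw(rng, rise_time, floor=0.2, n=n_cells)
    t50 = _draw(rng, t50_decay, floor=1.0, n=n_cells)
    base = _draw(rng, baseline, floor=50.0, n=n_cells)
    amp = _draw(rng, amplitude, floor=100.0, n=n_cells)
    sig = _draw(rng, footprint_sigma, floor=1.0, n=n_cells)
    n_resp = int(round(n_cells * responder_fraction))
    responder = np.zeros(n_cells, dtype=bool)
    responder[rng.permutation(n_cells)[:n_resp]] = True
    cells = []
    for i in range(n_cells):
        cells.append(
            CellTruth(
                center=(float(xs[i]), float(ys[i])),
                footprint_sigma=float(sig[i]),
                baseline=float(base[i]),
                amplitude=float(amp[i]) if responder[i] else 0.0,
                onset_latency=float(lat[i]),
                rise_time=float(rise[i]),
                t50_decay=float(t50[i]),
                responder=bool(responder[i]),
                label=f"cell{i:03d}",
            )
        )
    return cells


def transient_waveform(
    times: np.ndarray,
    onset_latency: float,
    rise_time: float,
    t50_decay: float,
    train: StimulusTrain,
    off_gain: float = 0.3,
) -> np.ndarray:
    """Unit-peak transient waveform locked to a stimulus train.

    Zero until ``train.onset + onset_latency``, linear rise over
    ``rise_time``, then exponential decay with half-life ``t50_decay``.
    During the off-periods of a phasic train the waveform is multiplied by
    ``off_gain``.
    """
    t = np.asarray(times, dtype=float)
    t_on = train.onset + onset_latency
    t_pk = t_on + rise_time
    w = np.zeros_like(t)
    rising = (t >= t_on) & (t < t_pk)
    w[rising] = (t[rising] - t_on) / rise_time
    decaying = t >= t_pk
    w[decaying] = np.exp2(-(t[decaying] - t_pk) / t50_decay)
    if train.pattern == "phasic" and off_gain != 1.0:
        stim_epoch = (t >= train.onset) & (t < train.end)
        off = stim_epoch & ~train.is_on(t)
        w[off] *= off_gain
    return w


def render_movie(
    truth: list[CellTruth],
    train: StimulusTrain,
    frame_shape: tuple[int, int] = (96, 128),
    frame_rate: float = 25.0,
    n_frames: int = 1500,
    noise: NoiseModel | None = None,
    background: float = 200.0,
    off_gain: float = 0.3,
) -> tuple[Movie, dict]:
    """Render a 16-bit fluorescence movie from ground-truth cells.

    The noiseless pixel expectation is ``background + sum_cells footprint *
    (baseline + amplitude * waveform(t))`` with unit-peak Gaussian
    footprints; shot/read noise, background drift and rigid jitter are
    applied afterwards.  Values beyond 65535 saturate with a warning.

    Returns the movie and a truth record holding the cells, the applied
    per-frame jitter, and the render parameters.
    """
    noise = noise or NoiseModel()
    h, w = frame_shape
    yy, xx = np.mgrid[0:h, 0:w]
    times = np.arange(n_frames) / frame_rate

    static = np.full((h, w), background, dtype=np.float64)
    footprints = []
    for cell in truth:
        cx, cy = cell.center
        if not (0 <= cx < w and 0 <= cy < h):
            raise ValueError(f"cell {cell.label!r} center outside the frame")
        fp = np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2)
                    / (2.0 * cell.footprint_sigma**2))
        footprints.append(fp)
        static += cell.baseline * fp

    waves = np.array([
        transient_waveform(times, c.onset_latency, c.rise_time, c.t50_decay,
                           train, off_gain=off_gain)
        for c in truth
    ])

    rng = np.random.default_rng(noise.seed)
    if noise.jitter_max > 0:
        jitter = rng.integers(-noise.jitter_max, noise.jitter_max + 1,
                              size=(n_frames, 2)).astype(float)
    else:
        jitter = np.zeros((n_frames, 2))

    drift = (noise.drift_amplitude * times / times[-1]) if n_frames > 1 else \
        np.zeros(n_frames)

    data = np.empty((n_frames, h, w), dtype=np.float32)
    saturated = False
    for f in range(n_frames):
        frame = static.copy()
        for fp, cell, wv in zip(footprints, truth, waves):
            if cell.amplitude > 0:
                frame += cell.amplitude * wv[f] * fp
        frame += drift[f]
        if jitter[f, 0] or jitter[f, 1]:
            frame = ndimage.shift(frame, (jitter[f, 0], jitter[f, 1]),
                                  order=1, mode="nearest")
        if noise.shot_noise:
            frame = rng.poisson(np.clip(frame, 0, None)).astype(np.float64)
        if noise.read_noise_sd > 0:
            frame = frame + rng.normal(0.0, noise.read_noise_sd, size=frame.shape)
        frame = np.rint(frame)
        if frame.max() > 65535:
            saturated = True
        data[f] = np.clip(frame, 0, 65535)
    if saturated:
        warnings.warn("synthetic movie saturated at 65535 iu16", stacklevel=2)

    movie = Movie(data=data, frame_rate=frame_rate, stim_onset=train.onset,
                  log=["synthetic render"])
    record = {
        "cells": truth,
        "jitter": jitter,
        "train": train,
        "off_gain": off_gain,
        "background": background,
        "noise": noise,
    }
    return movie, record


def render_contraction_video(
    truth: ContractionTruth,
    frame_rate: float = 25.0,
    n_frames: int = 1250,
    noise: NoiseModel | None = None,
    frame_shape: tuple[int, int] = (64, 512),
    pixel_scale: float = 10.0,
    landmark_sigma: float = 2.0,
    landmark_intensity: float = 30000.0,
    background: float = 2000.0,
) -> tuple[Movie, ContractionTruth]:
    """Render a brightfield video of two landmarks tracking a fatigue curve.

    The two high-contrast Gaussian blobs sit on a horizontal line and move
    symmetrically so that their center separation equals the truth distance
    series (to sub-pixel accuracy).  ``pixel_scale`` is um per pixel.
    """
    noise = noise or NoiseModel()
    h, w = frame_shape
    times = np.arange(n_frames) / frame_rate
    dist_px = truth.distance_series(times) / pixel_scale
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    x_left = cx - dist_px / 2.0
    x_right = cx + dist_px / 2.0
    if x_left.min() < 3 * landmark_sigma or x_right.max() > w - 1 - 3 * landmark_sigma:
        raise ValueError("landmarks leave the frame; enlarge frame_shape or "
                         "reduce rest_distance/pixel_scale")
    if dist_px.min() < 6 * landmark_sigma:
        raise ValueError("landmarks overlap at peak contraction")

    yy, xx = np.mgrid[0:h, 0:w]
    rng = np.random.default_rng(noise.seed)
    data = np.empty((n_frames, h, w), dtype=np.float32)
    landmarks = np.empty((n_frames, 2, 2))
    for f in range(n_frames):
        frame = np.full((h, w), background, dtype=np.float64)
        for j, x0 in enumerate((x_left[f], x_right[f])):
            frame += landmark_intensity * np.exp(
                -((xx - x0) ** 2 + (yy - cy) ** 2) / (2.0 * landmark_sigma**2)
            )
            landmarks[f, j] = (x0, cy)
        if noise.read_noise_sd > 0:
            frame = frame + rng.normal(0.0, noise.read_noise_sd, size=frame.shape)
        data[f] = np.clip(np.rint(frame), 0, 65535)

    truth_out = ContractionTruth(
        rest_distance=truth.rest_distance,
        peak_shortening=truth.peak_shortening,
        time_to_peak=truth.time_to_peak,
        ending_fraction=truth.ending_fraction,
        stim_onset=truth.stim_onset,
        stim_duration=truth.stim_duration,
        landmarks=landmarks,
    )
    movie = Movie(data=data, frame_rate=frame_rate,
                  stim_onset=truth.stim_onset, pixel_scale=pixel_scale,
                  log=["synthetic contraction render"])
    return movie, truth_out


#: Event waveform scales (mV, ms) measured at the P7 diaphragm NMJ.
DEFAULT_EVENT_PARAMS = {
    "ap": {"amplitude": 67.7, "rise_ms": 1.16, "t50_ms": 2.42},
    "epp": {"amplitude": 24.0, "rise_ms": 3.76, "t50_ms": 5.83},
    "mepp": {"amplitude": 2.52, "rise_ms": 3.76, "t50_ms": 5.83},
    "failed": {"amplitude": 12.0, "rise_ms": 3.76, "t50_ms": 5.83},
}


def _event_template(sample_rate: float, rise_ms: float, t50_ms: float) -> np.ndarray:
    """Unit-peak event waveform: linear rise then exponential decay."""
    rise_s = rise_ms / 1000.0
    t50_s = t50_ms / 1000.0
    dur = rise_s + 8.0 * t50_s
    t = np.arange(int(np.ceil(dur * sample_rate))) / sample_rate
    w = np.where(t < rise_s, t / rise_s, np.exp2(-(t - rise_s) / t50_s))
    return w


def simulate_sweeps(
    train: StimulusTrain | None,
    duration: float,
    sample_rate: float = 10000.0,
    rmp: float = -68.5,
    event_params: dict | None = None,
    failure_start_index: int | None = None,
    failure_mode: str = "subthreshold",
    mepp_rate: float = 0.0,
    noise_sd_mv: float = 0.0,
    seed: int = 0,
    cell_label: str = "cell0",
):
    """Simulate an intracellular voltage sweep with programmable AP failure.

    Each stimulus of ``train`` before ``failure_start_index`` elicits a
    suprathreshold muscle AP; from that index onward responses are
    subthreshold EPPs (``failure_mode="subthreshold"``), absent
    (``"absent"``), or alternate between the two (``"alternating"``).
    Spontaneous mEPPs are placed by a Poisson process at ``mepp_rate``
    events/s.  Deterministic given ``seed``.

    Returns
    -------
    (SweepSet, dict)
        The sweep and a truth record with per-stimulus success flags and
        mEPP times.
    """
    from .ephys import SweepSet  # local import to avoid a cycle

    if sample_rate < 1000:
        raise ValueError("sample_rate must be at least 1 kHz")
    params = dict(DEFAULT_EVENT_PARAMS)
    if event_params:
        params.update(event_params)
    for name, p in params.items():
        if rmp + p["amplitude"] > 60.0 or rmp < -120.0:
            raise ValueError(f"event class {name!r} drives Vm outside "
                             "[-120, +60] mV")

    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    rng = np.random.default_rng(seed)
    vm = np.full(n, rmp, dtype=np.float64)

    def _add(t0: float, p: dict) -> None:
        tmpl = _event_template(sample_rate, p["rise_ms"], p["t50_ms"])
        i0 = int(round(t0 * sample_rate))
        if i0 >= n:
            return
        seg = tmpl[: n - i0]
        vm[i0:i0 + len(seg)] += p["amplitude"] * seg

    stim_times: list[float] = []
    success: list[bool] = []
    if train is not None:
        for i, ts in enumerate(train.pulse_times):
            stim_times.append(float(ts))
            failed = failure_start_index is not None and i >= failure_start_index
            if failed and failure_mode == "alternating":
                failed = (i - failure_start_index) % 2 == 0
            if not failed:
                _add(ts, params["ap"])
                success.append(True)
            else:
                if failure_mode != "absent":
                    _add(ts, params["failed"])
                success.append(False)

    mepp_times = []
    if mepp_rate > 0:
        n_events = rng.poisson(mepp_rate * duration)
        mepp_times = np.sort(rng.uniform(0.0, duration, size=n_events))
        for tm in mepp_times:
            _add(float(tm), params["mepp"])

    if noise_sd_mv > 0:
        vm += rng.normal(0.0, noise_sd_mv, size=n)

    sweep = SweepSet(time=t, vm=vm, sample_rate=sample_rate,
                     stim_times=np.asarray(stim_times), cell_label=cell_label)
    record = {
        "success": np.asarray(success, dtype=bool),
        "mepp_times": np.asarray(mepp_times, dtype=float),
        "rmp": rmp,
        "event_params": params,
        "failure_start_index": failure_start_index,
        "failure_mode": failure_mode,
    }
    return sweep, record
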