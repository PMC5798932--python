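"""Statistical projection maps and per-ROI traces.

The standard-deviation map holds, at every pixel, the population SD of
intensity (SD iu16) over a window that opens shortly before the stimulus
(default 1.0 s) and extends 60 s past it, which highlights actively
fluorescing structures while being insensitive to exactly how much inactive
time is included.  Traces are per-ROI frame means, standardized either as
dF/F in percent against the pre-stimulus mean F_o, or as a peak
signal-to-noise ratio in decibels: dB = 20 * log10(peak excursion /
pre-stimulus trace SD), which expresses the peak of the Ca2+ event in units
of the noise that preceded it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .preprocess import Movie, Roi

__all__ = ["StatMap", "Trace", "sd_map", "mean_map", "roi_trace", "dff",
           "undo_dff", "to_decibels"]


@dataclass(frozen=True)
class StatMap:
    """A 2-D per-pixel statistic over a time window.

    ``statistic`` is ``"sd"`` (units SD iu16) or ``"mean"`` (units iu16);
    ``window`` is the (start, end) of the half-open time window in seconds.
    """

    data: np.ndarray
    statistic: str
    window: tuple[float, float]

    def __post_init__(self) -> None:
        if self.window[0] >= self.window[1]:
            raise ValueError("window start must precede window end")


@dataclass
class Trace:
    """A per-ROI time series with its pre-stimulus baseline statistics.

    ``values`` carries the current representation (raw iu16 or dF/F percent,
    see ``units``); when converted the raw series is retained in ``raw`` so
    conversions are non-destructive.  ``prestim_mean`` / ``prestim_sd`` are
    computed once, on the raw series, over the pre-stimulus window.
    """

    roi_label: str
    time: np.ndarray
    values: np.ndarray
    prestim_mean: float
    prestim_sd: float
    stim_onset: float
    units: str = "iu16"
    raw: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.time.shape != self.values.shape:
            raise ValueError("time and values must have the same length")
        if self.prestim_sd < 0:
            raise ValueError("prestim_sd must be >= 0")

    @property
    def frame_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.time)))


def _window_frames(movie: Movie, start: float, end: float) -> np.ndarray:
    t = movie.times
    sel = (t >= start - 1e-9) & (t < end - 1e-9)
    return sel


def _default_window(movie: Movie, window_start, window_end,
                    pre: float = 1.0, post: float = 60.0):
    if window_start is None:
        window_start = movie.stim_onset - pre
    if window_end is None:
        window_end = movie.stim_onset + post
    end_of_movie = movie.n_frames / movie.frame_rate
    return max(window_start, 0.0), min(window_end, end_of_movie)


def sd_map(movie: Movie, window_start: float | None = None,
           window_end: float | None = None) -> StatMap:
    """Per-pixel population standard deviation over a time window.

    The default window opens 1.0 s before stimulus onset and closes 60 s
    after it, clipped to the end of the movie.
    """
    start, end = _default_window(movie, window_start, window_end)
    sel = _window_frames(movie, start, end)
    if sel.sum() < 2:
        raise ValueError("SD window must contain at least 2 frames")
    data = movie.data[sel].astype(np.float64).std(axis=0, ddof=0)
    return StatMap(data=data, statistic="sd", window=(start, end))


def mean_map(movie: Movie, window_start: float | None = None,
             window_end: float | None = None) -> StatMap:
    """Per-pixel arithmetic mean over a time window (see :func:`sd_map`)."""
    start, end = _default_window(movie, window_start, window_end)
    sel = _window_frames(movie, start, end)
    if sel.sum() < 1:
        raise ValueError("mean window must contain at least 1 frame")
    data = movie.data[sel].astype(np.float64).mean(axis=0)
    return StatMap(data=data, statistic="mean", window=(start, end))


def roi_trace(movie: Movie, roi: Roi, prestim_window: float = 1.0) -> Trace:
    """Mean-intensity time series of a rectangular ROI.

    Pre-stimulus mean and (population) SD are computed over frames in
    ``[stim_onset - prestim_window, stim_onset)``; they are NaN when the
    movie has no pre-stimulus frames.
    """
    roi.validate(movie.shape)
    sl = roi.slices()
    vals = movie.data[:, sl[0], sl[1]].mean(axis=(1, 2), dtype=np.float64)
    t = movie.times
    sel = (t >= movie.stim_onset - prestim_window - 1e-9) & \
          (t < movie.stim_onset - 1e-9)
    if sel.any():
        pre_mean = float(vals[sel].mean())
        pre_sd = float(vals[sel].std(ddof=0))
    else:
        pre_mean = pre_sd = float("nan")
    return Trace(roi_label=roi.label, time=t, values=vals,
                 prestim_mean=pre_mean, prestim_sd=pre_sd,
                 stim_onset=movie.stim_onset)


def dff(trace: Trace) -> Trace:
    """Convert a raw trace to dF/F in percent.

    dF/F = 100 * (F(t) - F_o) / F_o with F_o the pre-stimulus mean; the raw
    series is retained on the returned trace.  Requires F_o > 0 on the raw
    (pre-static-subtraction) scale.
    """
    if trace.units != "iu16":
        raise ValueError("dff expects a raw iu16 trace")
    if not np.isfinite(trace.prestim_mean) or trace.prestim_mean <= 0:
        raise ValueError(
            "prestim mean F_o must be positive; compute dF/F on the raw, "
            "non-static-subtracted trace"
        )
    vals = 100.0 * (trace.values - trace.prestim_mean) / trace.prestim_mean
    return replace(trace, values=vals, units="percent",
                   raw=trace.values.copy())


def undo_dff(trace: Trace) -> Trace:
    """Inverse of :func:`dff`: recover the raw iu16 trace exactly."""
    if trace.units != "percent":
        raise ValueError("undo_dff expects a percent trace")
    vals = trace.prestim_mean * (1.0 + trace.values / 100.0)
    return replace(trace, values=vals, units="iu16", raw=None)


def to_decibels(trace: Trace, window_end: float | None = None) -> float:
    """Peak signal-to-noise ratio of a trace in decibels.

    dB = 20 * log10(peak excursion / prestim SD), where the excursion is the
    baseline-subtracted trace maximum from stimulus onset to ``window_end``
    (default: end of trace).  Ratios of 1, 10 and 100 map to 0, 20 and 40 dB.
    Returns NaN (with a warning) when the trace never rises above baseline.
    """
    if not np.isfinite(trace.prestim_sd) or trace.prestim_sd <= 0:
        raise ValueError("prestim_sd must be positive for a dB SNR")
    if trace.units == "percent":
        # same ratio on the percent scale: baseline 0, SD rescaled by F_o
        baseline = 0.0
        noise_sd = 100.0 * trace.prestim_sd / trace.prestim_mean
    else:
        baseline = trace.prestim_mean
        noise_sd = trace.prestim_sd
    sel = trace.time >= trace.stim_onset - 1e-9
    if window_end is not None:
        sel &= trace.time < window_end
    if not sel.any():
        raise ValueError("no samples in the analysis window")
    peak = float(np.max(trace.values[sel]) - baseline)
    if peak <= 0:
        warnings.warn("non-positive peak excursion; dB undefined "
                      "(non-responder)", stacklevel=2)
        return float("nan")
    return 20.0 * float(np.log10(peak / noise_sd))
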