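"""Optical quantification of muscle shortening and fatigue.

Two landmarks on the hemidiaphragm are tracked frame-by-frame by normalized
cross-correlation template matching (sub-pixel via parabolic refinement of
the correlation peak, search seeded at the previous position).  Their
separation, scaled to microns, gives the length-change series: length change
= distance(t) - pre-stimulus distance, so shortening is a negative number.
Fatigue is summarized as the ending length change -- the length change at
the last stimulated frame -- as a percentage of the peak length change; 100
minus that percentage is the failure to maintain peak shortening.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.feature import match_template

from .preprocess import Movie, Roi

__all__ = [
    "ContractionSeries",
    "TrackingLostError",
    "track_landmarks",
    "length_change_series",
    "fatigue_metrics",
    "multi_bout_summary",
]


class TrackingLostError(RuntimeError):
    """Raised when template correlation falls below the confidence floor."""

    def __init__(self, frame: int, confidence: float):
        self.frame = frame
        self.confidence = confidence
        super().__init__(
            f"landmark tracking lost at frame {frame} "
            f"(correlation {confidence:.3f})"
        )


@dataclass
class ContractionSeries:
    """Landmark-separation series with its pre-stimulus reference.

    ``distance`` in microns per frame; ``length_change`` = distance -
    pre-stimulus mean distance (negative = shortening); ``stim_end`` marks
    the last stimulated time for fatigue scoring.
    """

    time: np.ndarray
    distance: np.ndarray
    pixel_scale: float
    stim_onset: float = 0.0
    stim_end: float | None = None
    length_change: np.ndarray = field(init=False)
    reference: float = field(init=False)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.distance = np.asarray(self.distance, dtype=float)
        if (self.distance <= 0).any():
            raise ValueError("landmark distance must stay positive")
        pre = self.time < self.stim_onset - 1e-9
        self.reference = float(self.distance[pre].mean()) if pre.any() \
            else float(self.distance[0])
        self.length_change = self.distance - self.reference

    @property
    def peak_shortening(self) -> float:
        """Most negative length change, in microns."""
        return float(self.length_change.min())


def _subpixel_peak(corr: np.ndarray) -> tuple[float, float, float]:
    """(dy, dx, peak value) of the correlation maximum with per-axis
    parabolic refinement."""
    iy, ix = np.unravel_index(np.argmax(corr), corr.shape)
    peak = float(corr[iy, ix])
    dy, dx = float(iy), float(ix)

    def _refine(a, b, c):
        denom = a - 2 * b + c
        if denom >= 0:
            return 0.0
        return float(np.clip(0.5 * (a - c) / denom, -0.5, 0.5))

    if 0 < iy < corr.shape[0] - 1:
        dy += _refine(corr[iy - 1, ix], peak, corr[iy + 1, ix])
    if 0 < ix < corr.shape[1] - 1:
        dx += _refine(corr[iy, ix - 1], peak, corr[iy, ix + 1])
    return dy, dx, peak


def track_landmarks(
    video: Movie,
    templates: tuple[Roi, Roi],
    search_radius: int = 10,
    confidence_floor: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Track two point templates through a video.

    Each template patch is taken from the first frame at its ROI; in every
    subsequent frame it is located by normalized cross-correlation within a
    window of ``search_radius`` pixels around its previous position and
    refined to sub-pixel precision.  Raises :class:`TrackingLostError` when
    the best correlation drops below ``confidence_floor``.

    Returns
    -------
    (positions, confidences)
        ``positions`` of shape ``(n_frames, 2, 2)`` holding (x, y) of each
        landmark's template center per frame; ``confidences`` of shape
        ``(n_frames, 2)`` holding the correlation peak per landmark.
    """
    h, w = video.shape
    patches = []
    centers = []
    for roi in templates:
        roi.validate(video.shape)
        patches.append(video.data[0][roi.slices()].astype(np.float64))
        centers.append(np.array(roi.center, dtype=float))

    n = video.n_frames
    positions = np.empty((n, 2, 2))
    confidences = np.empty((n, 2))
    for f in range(n):
        frame = video.data[f].astype(np.float64)
        for j, patch in enumerate(patches):
            cx, cy = centers[j]
            ph, pw = patch.shape
            x0 = int(round(cx - (pw - 1) / 2.0)) - search_radius
            y0 = int(round(cy - (ph - 1) / 2.0)) - search_radius
            x0 = max(0, min(x0, w - pw - 2 * search_radius))
            y0 = max(0, min(y0, h - ph - 2 * search_radius))
            window = frame[y0:y0 + ph + 2 * search_radius,
                           x0:x0 + pw + 2 * search_radius]
            corr = match_template(window, patch)
            dy, dx, peak = _subpixel_peak(corr)
            if peak < confidence_floor:
                raise TrackingLostError(f, peak)
            cx = x0 + dx + (pw - 1) / 2.0
            cy = y0 + dy + (ph - 1) / 2.0
            centers[j] = np.array([cx, cy])
            positions[f, j] = (cx, cy)
            confidences[f, j] = peak
    return positions, confidences


def length_change_series(
    tracks: np.ndarray,
    pixel_scale: float,
    frame_rate: float,
    stim_onset: float,
    stim_end: float | None = None,
) -> ContractionSeries:
    """Build a :class:`ContractionSeries` from two landmark tracks.

    ``tracks`` has shape ``(n_frames, 2, 2)`` ((x, y) per landmark);
    ``pixel_scale`` is microns per pixel.  The reference distance is the
    mean over the pre-stimulus frames.
    """
    tracks = np.asarray(tracks, dtype=float)
    if pixel_scale <= 0:
        raise ValueError("pixel_scale must be positive")
    if tracks.ndim != 3 or tracks.shape[1:] != (2, 2):
        raise ValueError("tracks must have shape (n_frames, 2, 2)")
    sep = np.linalg.norm(tracks[:, 0, :] - tracks[:, 1, :], axis=1)
    time = np.arange(len(sep)) / frame_rate
    return ContractionSeries(time=time, distance=sep * pixel_scale,
                             pixel_scale=pixel_scale, stim_onset=stim_onset,
                             stim_end=stim_end)


def fatigue_metrics(series: ContractionSeries) -> dict:
    """Peak shortening and fatigue indices of one stimulation bout.

    ``ending_change_pct`` is the length change at the last stimulated frame
    as a percentage of the peak length change; ``failure_to_maintain_pct`` is
    100 minus that.  Raises when there was no contraction (zero peak).
    """
    lc = series.length_change
    peak = series.peak_shortening
    if peak == 0.0:
        raise ValueError("no contraction: peak length change is zero")
    if series.stim_end is not None:
        stim_frames = np.flatnonzero(series.time < series.stim_end - 1e-9)
        end_i = int(stim_frames[-1]) if len(stim_frames) else len(lc) - 1
    else:
        end_i = len(lc) - 1
    ending_pct = 100.0 * float(lc[end_i]) / peak
    return {
        "peak_shortening_um": peak,
        "ending_change_pct": ending_pct,
        "failure_to_maintain_pct": 100.0 - ending_pct,
    }


def multi_bout_summary(series_list: list[ContractionSeries],
                       bout_labels: list[str] | None = None) -> list[dict]:
    """Per-bout peak and ending metrics, peaks normalized to bout 1.

    Each bout's peak shortening is expressed as a percentage of the first
    (reference) bout's peak; ending metrics are per bout.
    """
    if len(series_list) < 2:
        raise ValueError("multi-bout summary needs at least 2 bouts")
    if bout_labels is None:
        bout_labels = [f"bout{i + 1}" for i in range(len(series_list))]
    ref_peak = series_list[0].peak_shortening
    if ref_peak == 0.0:
        raise ValueError("reference bout has zero peak shortening")
    rows = []
    for label, series in zip(bout_labels, series_list):
        m = fatigue_metrics(series)
        m["bout"] = label
        m["peak_pct_of_bout1"] = 100.0 * m["peak_shortening_um"] / ref_peak
        rows.append(m)
    return rows
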