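"""Fluorescence-movie conditioning.

The conditioning chain applied to GCaMP movies before any statistics are
computed: a 3x3 Gaussian filter (sd 1.0 px) against camera noise, rigid
motion correction by cross-correlation against a reference image,
stabilization of global background drift against a reference region (placed
near the main phrenic nerve branch in real recordings), and subtraction of
the pre-stimulus average image so that only structures that change intensity
-- the Ca2+ transients -- remain.

Movies are held as float32 stacks so that signed residuals after static
subtraction are preserved; raw 16-bit (or rescaled 8-bit) input is converted
on load.  Every operation returns a new :class:`Movie` and appends a line to
its provenance log.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.fft import fft2, ifft2

__all__ = [
    "Movie",
    "Roi",
    "gauss_filter",
    "estimate_and_apply_shifts",
    "stabilize_background",
    "prestim_average",
    "subtract_static",
]


@dataclass
class Movie:
    """A fluorescence or brightfield image stack with acquisition metadata.

    Attributes
    ----------
    data : numpy.ndarray
        ``(frames, height, width)`` float32 array in 16-bit intensity units
        (iu16); signed values are permitted after static subtraction.
    frame_rate : float
        Acquisition rate in frames per second.
    stim_onset : float
        Stimulus onset in seconds from the start of the recording.
    pixel_scale : float or None
        Microns per pixel, if known.
    log : list of str
        Ordered provenance of applied operations.
    """

    data: np.ndarray
    frame_rate: float
    stim_onset: float = 0.0
    pixel_scale: float | None = None
    log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(f"movie data must be 3-D, got shape {self.data.shape}")
        if self.frame_rate <= 0:
            raise ValueError(f"frame_rate must be positive, got {self.frame_rate}")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) of a frame."""
        return self.data.shape[1:]

    @property
    def times(self) -> np.ndarray:
        """Frame times in seconds (frame f at f / frame_rate, 0-based)."""
        return np.arange(self.n_frames) / self.frame_rate

    def frame_index(self, t: float) -> int:
        """Index of the frame at or just before time ``t``."""
        return int(np.floor(t * self.frame_rate + 1e-9))

    def with_data(self, data: np.ndarray, log_entry: str) -> "Movie":
        """Copy of this movie with new pixel data and an extra log line."""
        return replace(self, data=np.asarray(data, dtype=np.float32),
                       log=self.log + [log_entry])


@dataclass(frozen=True)
class Roi:
    """An axis-aligned region of interest.

    ``kind`` is ``"rectangle"`` for averaging regions or ``"point_template"``
    for landmark-tracking templates; geometry is identical (0-based pixel
    origin plus width/height).
    """

    x: int
    y: int
    width: int
    height: int
    label: str = ""
    kind: str = "rectangle"

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("roi width and height must be >= 1")
        if self.kind not in ("rectangle", "point_template"):
            raise ValueError(f"unknown roi kind {self.kind!r}")

    def validate(self, frame_shape: tuple[int, int]) -> None:
        h, w = frame_shape
        if self.x < 0 or self.y < 0 or self.x + self.width > w or self.y + self.height > h:
            raise ValueError(
                f"roi {self.label!r} ({self.x},{self.y},{self.width},{self.height}) "
                f"outside frame of shape {frame_shape}"
            )

    @property
    def center(self) -> tuple[float, float]:
        """(x, y) center in pixel coordinates."""
        return (self.x + (self.width - 1) / 2.0, self.y + (self.height - 1) / 2.0)

    def slices(self) -> tuple[slice, slice]:
        return (slice(self.y, self.y + self.height),
                slice(self.x, self.x + self.width))


def _gauss_kernel_3x3(sd: float = 1.0) -> np.ndarray:
    w = np.exp(-np.arange(-1, 2) ** 2 / (2.0 * sd**2))
    k = np.outer(w, w)
    return k / k.sum()


def gauss_filter(movie: Movie, sd: float = 1.0) -> Movie:
    """Convolve every frame with a unit-sum 3x3 Gaussian kernel (sd 1.0 px).

    Borders are handled by edge replication, so a constant frame is exactly
    preserved.
    """
    if movie.shape[0] < 3 or movie.shape[1] < 3:
        raise ValueError("frames must be at least 3x3 for the Gauss filter")
    kernel = _gauss_kernel_3x3(sd)
    out = np.empty_like(movie.data)
    for i in range(movie.n_frames):
        ndimage.correlate(movie.data[i], kernel, output=out[i], mode="nearest")
    return movie.with_data(out, f"gauss_filter(3x3, sd={sd})")


def _xcorr_shift(ref: np.ndarray, frame: np.ndarray, max_shift: int,
                 subpixel: bool) -> tuple[float, float]:
    """Translation (dy, dx) of ``frame`` relative to ``ref`` by the peak of
    the zero-mean cross-correlation surface (global gain/offset invariant)."""
    r = ref - ref.mean()
    f = frame - frame.mean()
    cc = np.real(ifft2(fft2(f) * np.conj(fft2(r))))
    cc = np.fft.fftshift(cc)
    cy, cx = np.asarray(cc.shape) // 2
    lo_y, hi_y = cy - max_shift, cy + max_shift + 1
    lo_x, hi_x = cx - max_shift, cx + max_shift + 1
    window = cc[lo_y:hi_y, lo_x:hi_x]
    iy, ix = np.unravel_index(np.argmax(window), window.shape)
    dy = float(iy - max_shift)
    dx = float(ix - max_shift)
    if subpixel:
        # parabolic refinement per axis, only strictly inside the window
        def _refine(vals: np.ndarray) -> float:
            denom = vals[0] - 2 * vals[1] + vals[2]
            if denom >= 0:
                return 0.0
            return float(np.clip(0.5 * (vals[0] - vals[2]) / denom, -0.5, 0.5))

        if 0 < iy < window.shape[0] - 1:
            dy += _refine(window[iy - 1:iy + 2, ix])
        if 0 < ix < window.shape[1] - 1:
            dx += _refine(window[iy, ix - 1:ix + 2])
    return dy, dx


def _shift_frame(frame: np.ndarray, dy: float, dx: float,
                 fill: np.ndarray) -> np.ndarray:
    """Translate a frame by (dy, dx); vacated margins take ``fill`` values."""
    if dy == 0.0 and dx == 0.0:
        return frame.copy()
    if float(dy).is_integer() and float(dx).is_integer():
        out = np.roll(frame, (int(dy), int(dx)), axis=(0, 1))
        nan_mask = np.zeros(frame.shape, dtype=bool)
        iy, ix = int(dy), int(dx)
        if iy > 0:
            nan_mask[:iy, :] = True
        elif iy < 0:
            nan_mask[iy:, :] = True
        if ix > 0:
            nan_mask[:, :ix] = True
        elif ix < 0:
            nan_mask[:, ix:] = True
        out[nan_mask] = fill[nan_mask]
        return out
    out = ndimage.shift(frame.astype(np.float64), (dy, dx), order=1,
                        mode="constant", cval=np.nan)
    bad = np.isnan(out)
    out[bad] = fill[bad]
    return out.astype(frame.dtype)


def estimate_and_apply_shifts(
    movie: Movie,
    reference: str | np.ndarray = "prestim_average",
    max_shift: int = 10,
    subpixel: bool = False,
    prestim_window: float = 1.0,
    refine_reference: bool = False,
) -> tuple[Movie, np.ndarray]:
    """Rigid motion correction against a reference image.

    Per-frame translation is estimated as the peak of the zero-mean
    cross-correlation surface against the reference (invariant to global
    intensity gain and offset), optionally refined to sub-pixel precision by
    parabolic interpolation.  Frames are shifted back and vacated margins are
    filled with the reference values.

    Alignment is only defined up to a global translation: a pre-stimulus
    average built from jittered frames is itself displaced, and that common
    offset cannot be recovered without ground truth.  ``refine_reference``
    re-derives a sharper reference from the first-pass correction and
    repeats the estimation, which helps when variable jitter has blurred
    the reference.

    Parameters
    ----------
    movie : Movie
    reference : {"prestim_average", "first_frame"} or ndarray
        Reference image to align to.
    max_shift : int
        Largest translation searched, pixels per axis.
    subpixel : bool
        Refine the correlation peak by parabolic interpolation.
    prestim_window : float
        Window (s) for the pre-stimulus average reference.
    refine_reference : bool
        Re-derive the reference from the first-pass correction and
        re-estimate (only when the reference is a named strategy).

    Returns
    -------
    (Movie, ndarray)
        Corrected movie and the per-frame estimated displacement table of
        shape ``(n_frames, 2)`` in (dy, dx) pixels; the applied correction is
        the negation of each row.
    """
    if movie.n_frames < 2:
        raise ValueError("motion correction needs at least 2 frames")

    def _resolve_reference(source: Movie) -> np.ndarray:
        if isinstance(reference, str):
            if reference == "prestim_average":
                return prestim_average(source, window=prestim_window)
            if reference == "first_frame":
                return source.data[0].astype(np.float64)
            raise ValueError(f"unknown reference {reference!r}")
        return np.asarray(reference, dtype=np.float64)

    def _one_pass(ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if ref.std() == 0:
            raise ValueError("featureless (zero-variance) reference image")
        shifts = np.zeros((movie.n_frames, 2), dtype=float)
        out = np.empty_like(movie.data)
        ref32 = ref.astype(np.float32)
        for i in range(movie.n_frames):
            dy, dx = _xcorr_shift(ref, movie.data[i].astype(np.float64),
                                  max_shift, subpixel)
            shifts[i] = (dy, dx)
            out[i] = _shift_frame(movie.data[i], -dy, -dx, ref32)
        return out, shifts

    out, shifts = _one_pass(_resolve_reference(movie))
    if refine_reference and isinstance(reference, str):
        first_pass = movie.with_data(out, "motion_correct pass 1")
        out, shifts = _one_pass(_resolve_reference(first_pass))
    corrected = movie.with_data(
        out, f"motion_correct(max_shift={max_shift}, subpixel={subpixel})"
    )
    return corrected, shifts


def prestim_average(movie: Movie, window: float = 1.0) -> np.ndarray:
    """Per-pixel mean over the pre-stimulus window.

    Averages all frames with time in ``[stim_onset - window, stim_onset)``.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if movie.stim_onset - window < -1e-9:
        raise ValueError(
            f"prestim window {window} s does not fit before stim_onset "
            f"{movie.stim_onset} s"
        )
    t = movie.times
    sel = (t >= movie.stim_onset - window - 1e-9) & (t < movie.stim_onset - 1e-9)
    if not sel.any():
        raise ValueError("no frames in the prestim window")
    return movie.data[sel].mean(axis=0, dtype=np.float64)


def stabilize_background(
    movie: Movie, reference_roi: Roi, prestim_window: float = 1.0
) -> Movie:
    """Cancel global background drift against a reference region.

    For each frame, the deviation of the reference-region mean from its
    pre-stimulus value is subtracted from every pixel, which removes any
    common additive per-frame offset exactly.  The reference region must not
    contain responding cells; if it does, their signal is subtracted from the
    whole movie (definitional misuse).
    """
    reference_roi.validate(movie.shape)
    sl = reference_roi.slices()
    ref_trace = movie.data[:, sl[0], sl[1]].mean(axis=(1, 2), dtype=np.float64)
    t = movie.times
    sel = (t >= movie.stim_onset - prestim_window - 1e-9) & \
          (t < movie.stim_onset - 1e-9)
    if not sel.any():
        raise ValueError("no frames in the prestim window")
    baseline = ref_trace[sel].mean()
    out = movie.data - (ref_trace - baseline)[:, None, None].astype(np.float32)
    return movie.with_data(
        out, f"stabilize_background(roi={reference_roi.label!r})"
    )


def subtract_static(movie: Movie, prestim_image: np.ndarray) -> Movie:
    """Subtract the pre-stimulus average image from every frame.

    Removes static fluorescent structures; pre-stimulus frames then
    fluctuate around zero and transients remain at their full amplitude.
    """
    prestim_image = np.asarray(prestim_image)
    if prestim_image.shape != movie.shape:
        raise ValueError(
            f"prestim image shape {prestim_image.shape} does not match "
            f"frame shape {movie.shape}"
        )
    out = movie.data - prestim_image.astype(np.float32)
    return movie.with_data(out, "subtract_static")
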