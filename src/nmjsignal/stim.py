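"""Nerve-stimulation protocols: tonic and phasic (duty-cycle) pulse trains.

The diaphragm preparation is driven either tonically (continuous pulse train,
e.g. 45 s at 40 Hz) or phasically, mimicking respiration: bursts with an
on-period (typically 100 ms) repeated at a duty cycle between 25% and 50%.
A train is fully described by its frequency, onset, duration, pattern and,
for phasic trains, the on-period length and duty cycle.  Pulses live on the
grid ``onset + k / frequency`` restricted to the half-open interval
``[onset, onset + duration)``; phasic trains keep only pulses falling in the
on-period of each cycle (cycle period = burst_on / duty_cycle, on-period
first).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["StimulusTrain", "build_train", "activity_mask"]

# tolerance (s) for putting grid times on interval/cycle boundaries
_TOL = 1e-9


@dataclass(frozen=True)
class StimulusTrain:
    """A pulse train with explicit pulse times.

    Attributes
    ----------
    frequency : float
        Pulse rate in Hz.
    onset : float
        Start of the train, seconds from recording start.
    duration : float
        Length of the stimulation epoch in seconds.
    pattern : str
        ``"tonic"`` or ``"phasic"``.
    burst_on : float
        On-period per cycle in seconds (phasic; equals ``duration`` for tonic).
    duty_cycle : float
        Fraction of each cycle that is active, in (0, 1] (1 for tonic).
    pulse_times : numpy.ndarray
        Ordered pulse times in seconds.
    """

    frequency: float
    onset: float
    duration: float
    pattern: str
    burst_on: float
    duty_cycle: float
    pulse_times: np.ndarray = field(repr=False)

    @property
    def end(self) -> float:
        return self.onset + self.duration

    @property
    def cycle_period(self) -> float:
        """Cycle period in seconds (burst_on / duty_cycle)."""
        return self.burst_on / self.duty_cycle

    @property
    def n_pulses(self) -> int:
        return len(self.pulse_times)

    def is_on(self, t: float | np.ndarray) -> np.ndarray:
        """True where time ``t`` falls inside an on-period of the train."""
        t = np.asarray(t, dtype=float)
        inside = (t >= self.onset - _TOL) & (t < self.end - _TOL)
        if self.pattern == "tonic":
            return inside
        phase = np.mod(t - self.onset, self.cycle_period)
        # fold boundary round-off back to phase zero
        phase = np.where(phase > self.cycle_period - _TOL, 0.0, phase)
        return inside & (phase < self.burst_on - _TOL)

    def on_fraction(self) -> float:
        """Fraction of the stimulation epoch that is active."""
        return 1.0 if self.pattern == "tonic" else float(self.duty_cycle)


def build_train(
    frequency: float,
    onset: float = 0.0,
    duration: float = 45.0,
    pattern: str = "tonic",
    burst_on: float | None = None,
    duty_cycle: float | None = None,
) -> StimulusTrain:
    """Enumerate every pulse of a tonic or phasic stimulation protocol.

    Parameters
    ----------
    frequency : float
        Pulse rate in Hz (> 0).
    onset, duration : float
        Stimulation epoch ``[onset, onset + duration)`` in seconds.
    pattern : str
        ``"tonic"`` for a continuous train; ``"phasic"`` for duty-cycle
        bursts, which additionally require ``burst_on`` and ``duty_cycle``.
    burst_on : float, optional
        On-period per cycle in seconds (phasic only), 0 < burst_on <= duration.
    duty_cycle : float, optional
        Active fraction of each cycle, in (0, 1] (phasic only).

    Returns
    -------
    StimulusTrain

    Examples
    --------
    0.1 s of 40 Hz tonic stimulation delivers four pulses:

    >>> build_train(40.0, 0.0, 0.1, "tonic").n_pulses
    4
    """
    if frequency <= 0:
        raise ValueError(f"frequency must be positive, got {frequency}")
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    if pattern not in ("tonic", "phasic"):
        raise ValueError(f"pattern must be 'tonic' or 'phasic', got {pattern!r}")

    if pattern == "tonic":
        burst_on = duration
        duty_cycle = 1.0
    else:
        if burst_on is None or duty_cycle is None:
            raise ValueError("phasic trains require burst_on and duty_cycle")
        if not (0.0 < duty_cycle <= 1.0):
            raise ValueError(f"duty_cycle must be in (0, 1], got {duty_cycle}")
        if not (0.0 < burst_on <= duration):
            raise ValueError(
                f"burst_on must be in (0, duration], got {burst_on}"
            )

    n = int(np.ceil(duration * frequency - _TOL))
    times = onset + np.arange(n) / frequency
    train = StimulusTrain(
        frequency=float(frequency),
        onset=float(onset),
        duration=float(duration),
        pattern=pattern,
        burst_on=float(burst_on),
        duty_cycle=float(duty_cycle),
        pulse_times=times,
    )
    if pattern == "phasic":
        keep = train.is_on(times)
        train = StimulusTrain(
            frequency=train.frequency,
            onset=train.onset,
            duration=train.duration,
            pattern=pattern,
            burst_on=train.burst_on,
            duty_cycle=train.duty_cycle,
            pulse_times=times[keep],
        )
    return train


def activity_mask(
    train: StimulusTrain, frame_rate: float, n_frames: int
) -> np.ndarray:
    """Per-frame boolean mask of stimulus on-periods.

    Frame ``f`` (time ``f / frame_rate``, 0-based) is True iff it falls
    inside an on-period of the train.  A zero-duration train yields all
    False.
    """
    if frame_rate <= 0:
        raise ValueError(f"frame_rate must be positive, got {frame_rate}")
    if n_frames < 1:
        raise ValueError(f"n_frames must be >= 1, got {n_frames}")
    t = np.arange(n_frames) / frame_rate
    if train.duration <= 0:
        return np.zeros(n_frames, dtype=bool)
    return train.is_on(t)
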