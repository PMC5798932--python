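import numpy as np
import pytest

from nmjsignal import Movie, Roi, build_train
from nmjsignal import synth

FRAME_RATE = 25.0


@pytest.fixture
def tonic_train():
    """Standard high-frequency stimulation epoch: 45 s of 40 Hz, onset 5 s."""
    return build_train(40.0, onset=5.0, duration=45.0, pattern="tonic")


@pytest.fixture
def phasic_train():
    """Respiration-like phasic train: 100 ms on-periods at 50% duty cycle."""
    return build_train(40.0, onset=5.0, duration=45.0, pattern="phasic",
                       burst_on=0.1, duty_cycle=0.5)


@pytest.fixture
def single_cell():
    return synth.CellTruth(
        center=(32.0, 24.0), footprint_sigma=3.0, baseline=1000.0,
        amplitude=2000.0, onset_latency=2.0, rise_time=3.0, t50_decay=12.0,
        responder=True, label="c0",
    )


@pytest.fixture
def noiseless_movie(tonic_train, single_cell):
    """Zero-noise single-responder movie; 60 s at 25 fps."""
    movie, record = synth.render_movie(
        [single_cell], tonic_train, frame_shape=(48, 64), n_frames=1500,
    )
    return movie, record


@pytest.fixture
def cell_roi():
    """25x25 window over the fixture cell's footprint (center 32, 24)."""
    return Roi(x=20, y=12, width=25, height=25, label="c0")


@pytest.fixture
def background_roi():
    return Roi(x=0, y=40, width=8, height=8, label="background")


def constant_movie(value=100.0, n_frames=50, shape=(8, 10),
                   frame_rate=FRAME_RATE, stim_onset=1.0):
    data = np.full((n_frames, *shape), value, dtype=np.float32)
    return Movie(data=data, frame_rate=frame_rate, stim_onset=stim_onset)


def make_trace(values, frame_rate=FRAME_RATE, stim_onset=5.0,
               prestim_window=None, label="t"):
    """Build a Trace with prestim stats over the full pre-onset epoch."""
    from nmjsignal import Trace

    values = np.asarray(values, dtype=float)
    t = np.arange(len(values)) / frame_rate
    if prestim_window is None:
        pre = t < stim_onset - 1e-9
    else:
        pre = (t >= stim_onset - prestim_window - 1e-9) & (t < stim_onset - 1e-9)
    return Trace(roi_label=label, time=t, values=values,
                 prestim_mean=float(values[pre].mean()),
                 prestim_sd=float(values[pre].std(ddof=0)),
                 stim_onset=stim_onset)
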