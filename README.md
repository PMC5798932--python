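# nmjsignal

Quantitative analysis of activity-evoked signaling at the neuromuscular
junction (NMJ): Ca²⁺ imaging of perisynaptic (terminal) Schwann cells
expressing a genetically encoded indicator, optical quantification of muscle
shortening and fatigue, and intracellular electrophysiology of endplate
potentials and muscle action potentials. The package is aimed at
physiologists analyzing fluorescence movies and voltage sweeps from
nerve–muscle preparations, and it ships a first-class synthetic-data module
so that every stage of the pipeline can be validated against known ground
truth without any recordings.

## What it computes

**Stimulation protocols.** Tonic trains (e.g. 45 s at 40 Hz) and phasic,
respiration-like trains (100 ms on-periods at a duty cycle *d*, cycle period
= on-period / *d*) with explicit pulse times on the grid
*t<sub>k</sub> = onset + k/f* over the half-open epoch `[onset, onset+duration)`.

**Movie conditioning.** The imaging chain: 3×3 Gaussian filter (σ = 1 px)
against camera noise → rigid motion correction by cross-correlation against
the pre-stimulus average → background stabilization against a reference
region → subtraction of the pre-stimulus average image, leaving only
structures that change intensity.

**Statistics.** Per-pixel standard-deviation projection maps (SD iu₁₆) over
a window from 1 s before stimulus onset to 60 s after; per-ROI traces with
ΔF/F₀ in percent (F₀ = pre-stimulus mean) and a decibel peak
signal-to-noise ratio,

&nbsp;&nbsp;&nbsp;&nbsp;dB = 20 · log₁₀(peak excursion / pre-stimulus SD),

which expresses a transient's peak in units of the noise that preceded it.

**Transient kinetics.** Responders are ROIs whose baseline-subtracted trace
exceeds *k*·SD<sub>prestim</sub> (default *k* = 3) for ≥ 2 consecutive
frames. Kinetics — onset latency, time to peak, time to 50% decay — are
scored by least-squares regression of the canonical transient template
(linear rise, exponential decay), initialized from the threshold-crossing
estimates.

**Contraction and fatigue.** Two landmarks tracked by normalized
cross-correlation template matching (sub-pixel); length change =
separation(t) − pre-stimulus separation (shortening is negative); fatigue
index = ending length change as % of peak length change, and 100 − that is
the failure to maintain peak shortening.

**Electrophysiology.** Event amplitude/rise/half-decay, mEPP frequency,
per-stimulus muscle-AP success (V<sub>m</sub> > RMP + 40 mV within 10 ms),
neural-transmission failure time (first trailing window of 8 stimuli with
< 50% success, reported at the earliest failed stimulus in that window),
EPP rundown (three-potential averages as % of the first three), the
−75…−60 mV RMP inclusion filter, and the Goldman–Hodgkin–Katz potential

&nbsp;&nbsp;&nbsp;&nbsp;V<sub>m</sub> = (RT/F) · ln[(P_K[K]ₒ + P_Na[Na]ₒ + P_Cl[Cl]ᵢ) / (P_K[K]ᵢ + P_Na[Na]ᵢ + P_Cl[Cl]ₒ)].

## Worked example

Render a noiseless movie of one responding Schwann cell (onset latency 2 s,
rise 3 s, half-decay 12 s), run the conditioning chain, and score the
transient:

```python
import numpy as np
from nmjsignal import (build_train, gauss_filter, estimate_and_apply_shifts,
                       stabilize_background, prestim_average, subtract_static,
                       roi_trace, detect_transient, Roi)
from nmjsignal import synth

train = build_train(40.0, onset=5.0, duration=45.0)        # 45 s of 40 Hz HFS
cell = synth.CellTruth(center=(32, 24), footprint_sigma=3.0, baseline=1000,
                       amplitude=2000, onset_latency=2.0, rise_time=3.0,
                       t50_decay=12.0, responder=True, label="c0")
movie, _ = synth.render_movie([cell], train, frame_shape=(48, 64), n_frames=1500)

m = gauss_filter(movie)
m, _ = estimate_and_apply_shifts(m)
m = stabilize_background(m, Roi(x=0, y=40, width=8, height=8, label="bg"))
m = subtract_static(m, prestim_average(m))

trace = roi_trace(m, Roi(x=20, y=12, width=25, height=25, label="c0"))
metrics = detect_transient(trace, train)
print(f"onset latency {metrics.onset_latency:.3f} s, "
      f"time to peak {metrics.time_to_peak:.3f} s, "
      f"t50 decay {metrics.t50_decay:.3f} s")
```

This prints

```
onset latency 2.001 s, time to peak 3.000 s, t50 decay 11.991 s
```

— the implanted kinetics recovered to within a fraction of a frame
(40 ms at 25 fps).

Counting pulses in a protocol from the shell:

```bash
$ nmjsignal stim-describe protocol.json
pattern: tonic
pulses: 4
on-fraction: 1.000
```

(for a 0.1 s, 40 Hz tonic protocol — four pulses).

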