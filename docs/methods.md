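# Methods

This note documents the models, estimators and numerical choices behind
`nmjsignal`, what the synthetic-data generators do and do not emulate, and
the known limitations of each stage.

## Stimulation model

A stimulus train is a pulse grid `t_k = onset + k/f` restricted to the
half-open epoch `[onset, onset + duration)`. The half-open convention is
what makes the pulse count of a 0.1 s train at 40 Hz exactly four — the
pulse at `t = 0.1 s` belongs to the next interval. Phasic (respiration-like)
trains keep only pulses falling in the on-period of each duty cycle; the
cycle period is `burst_on / duty_cycle` and each cycle begins with its
on-period, matching a stimulus that starts active. The phase of real
respiratory bursts relative to recording start is not observable from the
data this pipeline consumes, so "on-period first" is a convention, recorded
here. Frame mapping is `t = frame_index / frame_rate` with 0-based frames
throughout.

## Synthetic fluorescence movies

Each cell is an isotropic Gaussian footprint (somata are compact; shape
realism is irrelevant to metric testing) whose brightness follows the
canonical transient template: zero until the onset latency, a linear rise
over the rise time, then exponential decay with rate `ln 2 / t50`. This is
the simplest waveform with exactly the three degrees of freedom the
population statistics constrain — onset latency 1.8 ± 0.74 s after stimulus
onset, rise 2.86 ± 0.49 s, half-decay 13.35 ± 4.22 s — and those values are
the generator defaults. Kinetic fields are drawn independently per cell;
their true cross-correlations are unknown, which is an acknowledged
simplification. During the off-periods of a phasic train the waveform is
multiplied by an off-gain (default 0.3), so the per-cycle dropoff is
visible without the signal returning fully to baseline.

Noise is applied after the noiseless expectation is formed: optional
Poisson shot noise on the expected intensity, Gaussian read noise
(iu₁₆), a linear additive background ramp (`drift_amplitude` over the
recording), and rigid integer per-frame jitter up to `jitter_max` pixels,
recorded in the truth record. With all noise off, the rendered stack equals
the analytic model to rounding (±0.5 iu₁₆). Identical seeds give
bit-identical output. The generator does **not** emulate photobleaching,
non-rigid tissue motion, contraction-coupled focal shifts, heterogeneous
cell shapes, or temporally correlated camera noise — passing tests
therefore demonstrate correctness of the estimators under the stated noise
model, not robustness to every artifact of real recordings.

## Movie conditioning

* **Gauss filter.** A unit-sum 3×3 kernel with σ = 1.0 px, borders by edge
  replication (constant frames are preserved exactly; no zero-padding
  artifacts leak into SD maps).
* **Motion correction.** Rigid translation only. Each frame's displacement
  is the argmax of the zero-mean FFT cross-correlation against the
  reference (the pre-stimulus average by default), searched within
  ±10 px, optionally refined to sub-pixel by per-axis parabolic
  interpolation. Zero-meaning makes the estimate invariant to global gain
  and offset changes, so photobleaching-like intensity drift does not
  masquerade as motion. Vacated margins are filled with reference values.
  Alignment is defined only up to a global translation: a reference built
  from jittered frames is itself displaced, and that common offset is
  unrecoverable without ground truth (it is harmless downstream, since ROIs
  and statistics are computed in the corrected movie's own frame).
  `refine_reference=True` re-derives the reference from a first-pass
  correction when variable jitter has blurred it.
* **Background stabilization.** For each frame, the deviation of a
  reference-region mean from its pre-stimulus value is subtracted from
  every pixel; any additive per-frame offset common to all pixels cancels
  exactly. Registration runs first, stabilization second (the order is an
  explicit argument of the workflow, logged in provenance). The reference
  region must avoid responding cells and, under jitter, the frame margins.
* **Static subtraction.** The pre-stimulus average image (default window
  1.0 s before onset) is subtracted from every frame; signed residuals are
  kept — SD and ΔF computations need negative excursions, so intermediates
  are float32 and never clipped.
* **Bit depth.** All processing is on the 16-bit intensity scale; 8-bit
  TIFF input is linearly rescaled (×257) on load and logged, avoiding a
  second quantization.

## Statistical maps and traces

SD maps hold the per-pixel **population** standard deviation (divide-by-N)
over a window opening 1.0 s before stimulus onset and closing 60 s after
it, clipped to the movie. Population rather than sample SD because the map
is a descriptive projection of exactly the frames in the window, not an
estimate for a longer process; the convention is pinned by tests and the
window offsets are arguments. ΔF/F₀ is `100·(F−F₀)/F₀` with F₀ the
pre-stimulus trace mean, computed on the raw (pre-subtraction) scale; the
conversion retains the raw series, and its inverse is exact. The decibel
statistic is `20·log₁₀(peak excursion / prestim SD)` — a scale-free peak
signal-to-noise ratio: ratios of 1, 10, 100 give 0, 20, 40 dB, and scaling
the whole trace leaves it unchanged. For percent-unit traces the same
ratio is formed on the percent scale, so dB is representation-independent.

Trace baseline statistics default to the 1.0 s pre-stimulus window but the
window is an argument; the benchmark recordings here carry a 5 s
pre-stimulus epoch and use all of it, because the detection threshold
(below) is only as good as the SD estimate that scales it — with 25
baseline frames the sampling error of the SD inflates the false-positive
rate several-fold.

## Transient detection and kinetics

Detection: the baseline-subtracted trace must exceed `k × prestim SD`
(default k = 3) for at least 2 consecutive frames after stimulus onset,
with onset latency below a cap (stimulus duration + 2 s). On traces with a
5 s baseline this rule holds the false-responder rate below 1% on pure
noise while detecting every implanted responder at realistic amplitudes.
Increasing k can only remove responders (tested monotonicity). For
noiseless input the threshold scale is floored at machine level so any real
excursion still counts; dB is then undefined and reported as such.

Kinetic scoring has two modes. `refine="none"` scores directly from
samples: onset at the first threshold-crossing frame, peak at the sample
argmax, half-decay at the first linearly interpolated crossing of
half-amplitude after the peak (censored — reported absent — when the trace
is still above half-peak at the window end, which the slow decays here
often are). `refine="fit"` (default) refines those estimates by
least-squares regression of the transient template over the analysis
window, because the sample-based rules are noise-limited for slowly
decaying transients: near the peak the decay slope is ≈ A·ln2/t50 per
second, so with t50 ≈ 13 s even modest noise displaces the raw argmax by
seconds. The regression pools the whole trace and its accuracy degrades
roughly linearly with noise amplitude: in the recovery benchmark (100
cells at population-scale kinetics, 25 fps, 60 s traces) median absolute
errors are ≈ 0.07/0.12/0.55 s for latency / time-to-peak / t50 at 17 dB
trace SNR, and ≈ 0.03/0.05/0.13 s at 30 dB. The pinned benchmark runs at
30 dB — a clean-recording regime well above the 10 dB detection floor —
where all three medians sit inside two frames (0.08 s) for the onset terms
and 0.2 s for t50. The threshold rule alone decides responder status; the
regression only refines kinetics. The template fit assumes tonic drive;
for phasic traces use `refine="none"` or interpret fitted decay as an
effective value.

The per-cycle dropoff under phasic drive is quantified as the off/on ratio
of mean baseline-subtracted amplitude per duty cycle; a constant trace
reports ratio 1 by convention, and cycles before the transient peak mix
rise dynamics into the ratio, so analyses should judge post-peak cycles.

## Contraction and fatigue

Landmarks are template patches from the first frame, located per frame by
normalized cross-correlation (`skimage.feature.match_template`) within a
window around the previous position (tolerating large cumulative motion),
with per-axis parabolic sub-pixel refinement; a correlation below the 0.5
confidence floor raises a tracking-lost error carrying the frame index.
The reported position is the template center: if the template was grabbed
off the landmark's true center, tracks carry that constant offset, which
cancels in every distance-referenced statistic. Displacements are
recovered to ≲ 0.01 px RMS on synthetic videos at ~1% contrast noise.

Length change is `separation(t) − mean pre-stimulus separation`, scaled by
µm/px; shortening is negative. The fatigue index is the ending length
change — at the **last stimulated frame**, not the last video frame, so
post-stimulus relaxation cannot contaminate it — as a percentage of peak
length change; `100 −` that is the failure to maintain peak. Multi-bout
summaries normalize each bout's peak to the first bout's. Percentages are
invariant to uniform scaling; absolute µm values depend on the pixel
scale, which real recordings must supply.

The synthetic videos place two high-contrast Gaussian landmarks whose
separation follows a piecewise-linear contraction–fatigue curve (rise to
peak, linear fatigue decline to `ending_fraction × peak` at stimulation
end, exponential relaxation after); defaults are the measured scales
(rest separation 4 mm, peak shortening ≈ 752 µm, 72.6% maintained). Real
videos add out-of-plane motion, non-rigid deformation and illumination
changes that the generator does not model.

## Electrophysiology

Events are scored against a local baseline (mean over 5 ms before the
event): onset at the first departure above 2× baseline SD sustained for 2
samples, amplitude = peak − baseline, rise to peak from onset, half-decay
by linear interpolation after the peak. Synthetic events use the same
linear-rise/exponential-decay template at unit peak, with measured scales
as defaults: EPP 24 mV; AP 67.7 mV, rise 1.16 ms, half-decay 2.42 ms; mEPP
2.52 mV at 0.38 events/s (Poisson). At the 10 kHz default sampling the
0.1 ms quantization bounds rise-time accuracy.

A stimulus is a successful muscle AP when V<sub>m</sub> exceeds
RMP + 40 mV within 10 ms (both arguments); the 40 mV criterion cleanly
separates full APs (~68 mV) from subthreshold endplate responses
(~10–25 mV) but is an operational rule, not a biophysical definition.
Neural-transmission failure is declared at the first trailing window of 8
stimuli with under half successes; the reported time is the earliest
failed stimulus inside that triggering window, which localizes a
programmed failure onset exactly (index error 0) rather than lagging by
half a window. The window length trades latency against robustness to
isolated failures and is an argument. Rundown follows the three-potential
averaging rule (mean of three at an index as % of the mean of the first
three), scale-invariant by construction. The RMP inclusion filter keeps
fibers in the closed interval [−75, −60] mV; closed because a fiber at
exactly −60 mV satisfies "between −60 and −75".

The GHK potential uses RT/F in mV with temperature an explicit argument
(default 310 K; room-temperature comparisons must say so). With a single
permeant ion it reduces to the Nernst potential to machine precision, and
it is strictly increasing in [K⁺]ₒ; the 5→10 mM step at 310 K predicts a
+18.5 mV depolarization, the quantity used for potassium-challenge
comparisons.

## Problem sizes and reproducibility

The shipped benchmarks use 48×64–96×128 px movies at 25 fps (≤ 1500
frames), 64×512 px videos (≤ 1250 frames), and 10 kHz sweeps (≤ 200 s);
these sizes keep the full validation suite and the acceptance script fast
on a single core while leaving every estimator in its asymptotic regime
(the statistics scale with window lengths, not frame area). All generators
are seeded; `scripts/acceptance.py` derives every sub-seed from its
`--seed` argument, so its JSON output is exactly reproducible.

## Known limitations

* Rigid, translation-only registration; rotation or non-rigid warp is out
  of scope.
* The kinetic regression assumes one transient per bout; multi-transient
  decomposition and spike inference are out of scope.
* F_max normalization (saturating the indicator pharmacologically) is not
  implemented: no downstream statistic consumes it.
* Per-frame trace values are intensities; SD is only ever a window
  statistic, never a per-sample unit.
* Absolute contraction distances require a supplied pixel scale; only the
  percentage statistics are scale-free.
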