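# Methods

`semgfat` classifies four dynamic muscle-fatigue states — relaxed, a
little tired, very tired, extremely tired — from 6-channel surface EMG
(sEMG) recorded during isokinetic knee flexion/extension at 60°/s or
180°/s. Because the human-subject data the method was designed around is
not available, the package ships a synthetic sEMG generator with the
statistical structure the method assumes, and every model is exercised
end to end on it. This note records the model, the defaults and why,
what the simulator does and does not emulate, and the numerical and
design choices that were genuinely open.

## 1. Signal model of the simulator

One *action cycle* is a complete knee flexion+extension (3 s at 60°/s,
1 s at 180°/s); a session is 40 consecutive maximal cycles. Per cycle
`k` (0-based) and muscle, the generator draws white Gaussian noise and
shapes it in the frequency domain with an amplitude envelope

    H_k(f) = B(f) · exp(−c · k · r(f)) / ||·||,

where `B(f)` is a raised-cosine band-pass over 10–250 Hz (the usual
surface-EMG band), `r(f)` ramps linearly from 0 at 20 Hz to 1 at 250 Hz,
and `c` is the per-cycle compression rate. The envelope is normalised to
unit power each cycle, so compression redistributes spectral energy
toward low frequencies without draining it — the defining signature of
myoelectric fatigue (motor-unit conduction-velocity slowing). Overall
amplitude instead rises deterministically by `amplitude_drift` per cycle
(constant-effort contractions recruit harder as the muscle tires).

The six sources are mixed by a full-rank, diagonally dominant matrix
(`exp(−|i−j|/1.5)`, rows unit-norm) emulating electrode cross-talk, and
each channel is amplitude-modulated by a raised-cosine activation burst.
The burst carries a second, spatio-temporal fatigue signature:
its width grows by `burst_width_drift` per cycle and its peak drifts in
time by `burst_timing_drift` per cycle — later for the extensor channels
(0–2), earlier for the flexors (3–5) — emulating the coordination
changes of tiring muscles. This component is deliberate: it is class
information that lives below the 10 Hz band edge, invisible to the
band-power entropy features but readable by a spatio-temporal network,
which is the regime the method comparison is about. White measurement
noise is added at `noise_floor` of the signal power.

Subjects differ by a log-normal amplitude factor (σ = 0.3) and Gaussian
jitter on the mixing entries (σ = 0.05); the Borg RPE rating ramps
linearly 6 → 20 over the session (quantised to integers). Everything is
a pure function of `(SimConfig, subject_id)`; per-subject streams are
derived from the config seed and a CRC of the subject label.

Defaults and their provenance:

| parameter | default | why |
| --- | --- | --- |
| `n_cycles` | 40 | protocol: 40 maximal movements per session |
| `sampling_rate` | 1000 Hz | covers the 10–250 Hz sEMG band |
| `fatigue_compression_rate` | 0.35 /cycle | calibrated so the simulated PSE/WPE fitting slopes at 60°/s (≈ −0.013 and −0.012 per movement) approach the reported −0.0156 / −0.0144; the slope saturates for stronger compression because entropy floors near 0.5 |
| `amplitude_drift` | 0.01 /cycle | ≈ +40% RMS over the session, typical for exhaustive constant-effort protocols |
| `burst_width_drift` | 0.004 /cycle | +16% burst width over the session — moderate coordination change |
| `burst_timing_drift` | 0.002 /cycle | ±8% of the cycle (±240 ms at 60°/s) peak shift by the end |
| `noise_floor` | 0.05 | 5% measurement-noise power |
| `amplitude_scale_sigma` | 0.3 | inter-subject amplitude spread, exercises %MVC normalisation |

The MVC benchmark is generated as a separate pre-test: four extra
fresh-state maximal cycles per subject; the per-channel reference is the
mean over them of the peak 100 ms moving RMS ("mean dynamic MVC").

What the simulator does **not** emulate: motor-unit recruitment and
firing statistics, force/torque coupling, electrode artefacts and ECG
contamination, non-stationarity within a cycle beyond the burst shape,
day-to-day electrode placement variability, and any within-subject
correlation structure richer than the deterministic drifts above. A
green end-to-end test therefore establishes that the pipeline recovers
the structure this world contains — not that the reported human-subject
accuracies are reproducible (see §6).

## 2. Preprocessing

Each channel is normalised to `%MVC = signal / MVC × 100`. One window is
cut per action cycle. The stored window is the 25 ms moving-RMS envelope
of the %MVC signal over the **whole cycle**, polyphase-resampled
(time-normalised) to the model's fixed input shape: 6×120 at 60°/s,
6×160 at 180°/s. Two readings of the original preprocessing
description were
possible — a fixed 1 s / 250 ms raw-signal excerpt, or a
time-normalised whole-cycle representation; both remain available (`window_len=`,
`envelope_ms=None`). The whole-cycle envelope is the default because
(a) at 40–160 samples per second only envelope content is representable
at all (raw sEMG needs ≥ 500 Hz), and (b) a network whose hidden units
are odd functions about their midpoint (scaled tanh, sigmoid) has
provably class-independent expected activations on sign-symmetric
zero-mean inputs, and measurably never leaves the class-prior plateau
when trained on resampled raw oscillations.

RPE → class: 6–12 relaxed, 13–16 a little tired, 17–18 very tired,
19–20 extremely tired (the experiment's rating instrument); the variant
binning 17–19 / 20 that the original description also mentions is
available as `LabelScheme.o5_variant()`.

Split: the windows of 60 of the 64 subjects are pooled, shuffled once
with the split seed, and cut into five equal segments assigned 3:1:1
(train/validation/test) — so test shares subjects, never windows, with
training. The remaining 4 subjects are held out entirely and measure
subject-level generalisation, mirroring the original design (whose
held-out-subject accuracy was below its test accuracy, which is only
possible if its test split shared subjects). `mode="by_subject"` gives
the fully cross-subject split instead.

## 3. Entropy features

Both nonlinear indices share one functional. A segment's energy is
distributed over `z` sub-bands, normalised to probabilities
`Px = Ex / ΣEx`, and scored by the Shannon entropy with base-`z`
logarithm, so 1 means maximally uniform (complex, unfatigued) and 0
means fully concentrated. The base-`z` choice is what makes traces
comparable across band schemes; natural log is available.

* **PSE** takes `Ex` from the FFT periodogram (bins outside the scheme
  are excluded).
* **WPE** takes `Ex` from a wavelet-packet decomposition implemented in
  the package: orthonormal Daubechies filters (db4 default; haar/db2
  available), periodic boundary after symmetric padding to a multiple of
  `2^depth`, terminal nodes in frequency order. Node energies equal
  reconstructed-signal energies by orthogonality, so no explicit
  reconstruction is performed, and the transform is exactly unitary —
  node energies sum to the (padded) segment energy to machine precision.
  Terminal nodes are pooled into the scheme's sub-bands by centre
  frequency; out-of-range nodes pool into the nearest edge band, which
  preserves total energy for any scheme. The decomposition depth adapts
  to resolve the narrowest band (plus `wp_depth` refinement), capped by
  the segment length.

The default band scheme is eight unequal sub-bands with edges
10, 20, 35, 55, 80, 110, 150, 200, 250 Hz — narrower at low frequencies,
where fatigue concentrates power, so compression moves energy into
*fewer* bands and both entropies fall. Band widths were described as
experimenter-adjusted in the original experiment; these values are a
standard choice,
fully configurable.

Per-cycle traces are computed on the %MVC-normalised native-rate signal
(not the stored windows). `trend_stats` reports the Pearson correlation
of entropy vs movement number with its two-sided p-value and the
least-squares line; a constant trace returns r = 0, p = 1 with a
degenerate flag. The classical classifiers consume the per-cycle
12-vector (PSE and WPE of the six muscles, fixed channel order).

## 4. The CNN

Five layers, implemented from scratch in NumPy with exact analytic
backpropagation:

* **I1**: 6×T window (T = 120 or 160), scaled by `input_scale = 0.05` so
  %MVC-valued inputs land in the operating range of the first
  activation (selected by validation loss; pure conditioning, no
  architectural change).
* **C2**: ten 6×1 kernels spanning all channels at one time point
  (purely spatial filtering), shared bias per map, activation
  `f(x) = a·tanh(b·x)` with a = 1.71159, b = 2/3. Output: ten 1×T maps.
  A per-position bias reading of the layer's transfer notation is
  rejected in favour of the standard
  shared per-map bias, consistent with the shared-weight learning-rate
  rule.
* **C3**: four 1×10 kernels per C2 map, stride 10, no padding
  (convolution-pooling): forty 1×(T/10) maps, scaled tanh.
* **F4**: 100 sigmoid units fully connected to all 40·(T/10) C3
  activations (the stated full connection supersedes index bounds in
  the transfer notation that conflict with the C3 map length).
* **O5**: 4 sigmoid outputs, one per fatigue class; argmax predicts,
  ties resolve to the lowest class index.

Loss: mean squared error against one-hot targets, averaged over samples
and output units (softmax + cross-entropy selectable; the gradient
check covers both pairings). Initialisation: every weight and bias
uniform in ±1/√fan-in (±1/fan-in behind a flag). Learning rates follow
the layer-wise rule — shared-weight layers γ = 2λ/(N_shared·√fan-in)
with N_shared the positions sharing a kernel (T for C2, T/10 for C3);
dense layers γ = λ/√fan-in. One iteration is one full-batch gradient
step (deterministic; seeded mini-batches available). Validation loss is
evaluated every 10 iterations and the parameters at its first strict
minimum are returned with the full loss history.

The base rate λ is the one genuinely free optimisation constant. Under
the layer-wise scalings above, λ = 0.05 yields dense-layer rates of
~0.002 and makes no measurable progress within a CPU-scale budget; a
validation-loss grid selected λ = 10 (with the 0.05 input scale), which
the default run configuration uses. The default training budget is
2500 full-batch iterations: on the default cohort the validation loss
reaches its minimum near iteration 2100 and rises afterwards, so longer
budgets (measured to 6000; the original design allowed 10,000) only add
overfitting tail at single-CPU cost.

## 5. Baselines and evaluation

**Multi-SVM**: Gaussian kernel `K(x,y) = exp(−‖x−y‖²/σ²)` (written
here with the explicit minus sign — a positive exponent would not be a
decaying similarity), one-vs-one voting, features z-scored on training
statistics. σ and C are selected on the validation set over a log-spaced
grid (σ ∈ [0.1, 10], C ∈ {0.1, 1, 10, 100}) when not fixed. The
quadratic-program solver is scikit-learn's SVC; kernel parametrisation,
scaling and model selection are package code.

**Multi-LDA**: Fisher discriminant implemented directly — between-class
and within-class scatter from the class means, projection = leading 3
generalized eigenvectors of `S_B w = λ S_W w`, nearest class centroid in
the projected space (negative distances serve as class scores). A
singular `S_W` triggers flagged shrinkage regularisation.

**Metrics**: accuracy = confusion-matrix trace over total. For
single-label multiclass data, micro-precision, micro-recall and
micro-F1 pool per-class TP/FP/FN and all equal accuracy; the package
computes them independently in exact rational arithmetic so the
identity holds bit-for-bit. ROC is one-vs-rest per class by threshold
sweep with trapezoid AUC (equal to the tie-aware Mann–Whitney pairwise
statistic), macro-averaged on a common FPR grid (micro pooling behind a
flag — the multiclass reduction is a convention, not part of the
method).
Held-out-subject dispersion is reported as mean ± sample standard
deviation (ddof = 1).

## 6. Known limitations

* The four-class accuracy attainable in the synthetic world is bounded
  by per-cycle estimator noise: a window of band-limited noise carries
  power and spectral-shape estimates with ~2·B·T degrees of freedom, so
  single-cycle features resolve the movement index to roughly ±2
  cycles, while the two hardest classes are only 5 cycles wide. The
  entropy-feature classifiers operate near that bound (~0.90 test
  accuracy); the CNN sees the same cycles only through the 120/160
  sample windows and lands a few points below. The reported human-data
  ordering (CNN above both baselines) is not reproduced by the default
  world, and the corresponding acceptance check is left failing rather
  than engineered to pass: making the CNN win would require either
  giving it native-rate inputs the fixed 6×120 / 6×160 input shapes
  do not admit,
  or inflating the burst-shape drift beyond what was fixed a priori.
* Wavelet-packet band energies are pooled by node centre frequency;
  bands narrower than the reachable node width on short segments raise
  an explicit error rather than silently blending.
* The reported per-muscle trend correlations could not be used as a
  noise calibration anchor: their reported p-values are inconsistent
  with 40-point per-cycle traces, so per-cycle trace noise is whatever
  the signal model implies, and simulated per-trace |r| (~0.97) is
  higher than the reported per-muscle values.
* Training the CNN to its 10,000-iteration budget on the full cohort
  takes ~25 CPU-minutes; defaults trade a few accuracy points for a
  ~9-minute end-to-end run.
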