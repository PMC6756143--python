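# Methods

## Problem setting

Sleep apnea (SA) screening from a single ECG lead is framed as per-minute
binary classification. A recording is a 100 Hz single-lead ECG with one
apnea/normal label per elapsed minute. Per-minute predictions aggregate into
a per-recording diagnosis through the apnea–hypopnea index,
AHI = 60/T × (number of apnea minutes) over T labeled minutes, with SA
declared when AHI > 5 events/hour. Severity classes follow the public
apnea-ECG benchmark convention: class A when AHI ≥ 10 and the recording holds
at least 100 apnea minutes, class C when AHI < 5, class B otherwise. The
printed A/B/C definitions of that benchmark leave gaps (e.g. AHI between 5
and 10 with ≥ 100 apnea minutes fits no class by the letter); the rule used
here — A iff (AHI ≥ 10 and n ≥ 100), else B iff AHI ≥ 5, else C — covers
every (T, n) pair exactly once and reproduces the benchmark classes on its
own cohort ranges.

Event-interval annotations (onset + duration per apnea/hypopnea episode) are
converted to per-minute labels with the 5-second rule: minute m = [60m,
60(m+1)) is apneic iff some single event overlaps it by at least 5 s. The
rule is applied per event, not to the union of several short events — the
closest reading of "apnea or hypopnea lasting 5 or more consecutive seconds";
a 6-second event split 2 s + 4 s across a minute boundary therefore marks
neither minute.

## Preprocessing

1. **R-peak detection.** A Hamilton-style detector: zero-phase Butterworth
   band-pass 8–16 Hz (order 2), differentiation, rectification, 80 ms
   moving-window integration, then local maxima of the envelope accepted
   against an adaptive threshold `noise + 0.3125 × (signal − noise)` with
   running exponential estimates (weight 0.125) and a 200 ms refractory
   distance. Detections are refined to the raw-signal maximum within
   ±100 ms, so reported amplitudes are raw R-peak values (no baseline
   subtraction). The detector sits behind a pluggable function contract;
   an all-flat signal yields an empty series rather than an error.
2. **RR/amplitude series.** RR intervals are successive peak-time
   differences, stamped at the later peak (the interval exists only once the
   second beat has occurred); the amplitude channel takes the value at that
   later peak.
3. **Median filtering.** RR values deviating from the median of their
   centred 5-sample window by more than 20% of that median are replaced by
   the median (length-preserving; amplitudes untouched). Window and
   tolerance are exposed as arguments.
4. **Uniform resampling.** Cubic-spline interpolation of both series onto a
   3 Hz grid — the rate that turns a 5-minute span into exactly 900 points
   per channel. Grid times outside the support range take the nearest
   support value; there is no spline extrapolation.
5. **Window assembly.** Each labeled minute yields a tensor over the minute
   plus its two neighbours on each side (context ±2). For the first and last
   two minutes the nominal grid is kept and out-of-range points replicate
   the boundary values, so every annotated minute gets a full 900-point
   window and hence a prediction — necessary for AHI accounting. Dropping
   edge minutes instead would be defensible; replication was chosen so that
   per-recording AHI sums over all T minutes.

## The classifier

A LeNet-5 adapted to one-dimensional two-channel input:

| layer | parameters | output shape | trainable |
|---|---|---|---|
| input | – | (900, 2) | 0 |
| conv1d | 32 filters × kernel 5 × 2 ch, stride 2 | (448, 32) | 352 |
| max-pool | 3, stride 3 | (149, 32) | 0 |
| conv1d | 64 filters × kernel 5 × 32 ch, stride 2 | (73, 64) | 10 304 |
| max-pool | 3, stride 3 | (24, 64) | 0 |
| dropout | drop probability 0.8 | (24, 64) | 0 |
| dense | 32, relu | (32,) | 49 184 |
| output | 2, softmax | (2,) | 66 |

Output lengths follow `floor((L + 2p − k)/s) + 1` with no padding; the
second convolution spans all 32 incoming feature maps (its 10 304-parameter
count confirms full-channel fan-in). "Dropout rate 0.8" is read as the
probability of zeroing a unit (inverted scaling at train time). Both
convolutions use relu. The loss is the categorical cross entropy
J(ω,b) = −(1/N) Σ_l Σ_k y_{lk} log ŷ_{lk} with ŷ the softmax of the output
scores, computed with max-subtraction and an ε-clamp on log arguments.

The network is implemented directly on NumPy arrays (strided sliding-window
views for the convolutions; analytic backward passes verified against finite
differences in the test suite). Training uses Adam (lr 1e-3, β = 0.9/0.999),
batch 128, up to 100 epochs by default with early stopping (patience 10) on
a 10% random validation split, all driven by one seeded generator so a fixed
seed reproduces the loss history bit for bit. Weights use He initialization
except the softmax head, which starts near zero so the initial loss of a
balanced problem sits at ln 2. Class reweighting is available but off by
default. Hard labels threshold the apnea probability at 0.5; ROC/AUC uses
the continuous probability.

In the experiment harness, window channels are standardized (per-channel
mean/sd from the training recordings) before entering the network — a
conditioning choice for the raw-unit RR/amplitude scales, fitted on training
data only.

## HRV feature baselines

Eighteen features per window, computed over the full 5-minute span (matching
the CNN's receptive field): RMSSD, SDNN, NN50 (successive differences
strictly exceeding 50 ms), pNN50 (NN50 over the interval count), mean RR,
mean HR from the filtered RR intervals inside the span; and for each of the
two interpolated channels, normalized VLF/LF/HF band powers, LF/HF,
LF/(LF+HF) and HF/(LF+HF). SDNN follows the feature table's wording —
standard deviation of the *successive differences* — with a
`sdnn_convention="classic"` switch for the usual std-of-intervals reading.
Spectra come from Welch's method on the 3 Hz series (segment 256, 50%
overlap, mean detrend); band edges are the standard short-term HRV bands
0.003–0.04 / 0.04–0.15 / 0.15–0.4 Hz, exposed as configuration since the
source feature set does not pin them. A constant channel has no oscillatory
power: all six spectral outputs are zero, with a warning.

Min-max normalization x* = (x − x_min)/(x_max − x_min) is fitted on training
rows only; zero-range columns map to 0 and test values may leave [0, 1].
The four baselines are scikit-learn estimators — SVM (RBF, C = 1), logistic
regression (L2), KNN (k = 5), MLP (one hidden layer of 32) — behind a
uniform fit/predict contract returning hard labels plus a continuous score
for ROC analysis. Hyperparameters are defaults of convenience, seeded and
configurable.

## Evaluation

Specificity TN/(TN+FP), sensitivity TP/(TP+FN) and accuracy with apnea as
the positive class; undefined ratios surface as NaN rather than exceptions.
AUC is the rank-based (Mann–Whitney) area, delegated to scikit-learn and
cross-checked in the tests against exhaustive concordant-pair counting.
Per-recording analysis applies the AHI > 5 rule to both predicted and expert
labels (the same rule defines truth) and reports the recording-level
confusion, metrics, AUC with estimated AHI as the score, and the Pearson
correlation between estimated and true AHI. Cross-validation shuffles
recordings with a fixed seed and partitions them into folds, so no recording
contributes minutes to both sides of a fold; stratification by severity
class is deliberately not applied by default (plain random grouping).

## The simulator

The generator emulates exactly the signal features the pipeline is designed
to detect, and no more. Beats are placed by integrating an instantaneous
heart rate: base 70 bpm with 1 bpm per-beat Gaussian jitter; during apnea
minutes a sinusoidal swing of ±10 bpm with a 45 s period (≈ 0.022 Hz, inside
the VLF band — the cyclic bradycardia–tachycardia pattern of apneic sleep),
and R-amplitudes modulated ±30% at the same phase. Each beat is rendered as
a fixed narrow biphasic QRS-like template (12 ms Gaussian R lobe with a
small trailing dip) on Gaussian noise of sd 0.05; beat times snap to the
sample grid so ground truth is expressible in samples. Apnea minutes are
placed as multi-minute bouts (runs of 2–6 minutes) totalling the requested
fraction, and the event list is exactly those contiguous bouts, so the
5-second conversion rule reproduces the labels identically. Cohorts draw
each recording's apnea-minute count from the feasible range of its requested
severity class and verify the class post hoc; record i uses seed
`base_seed + i`.

What the simulator does **not** model: realistic P-QRS-T morphology, ectopic
beats, baseline wander, electrode artefacts, obstructive-vs-central event
structure, or sleep-stage dependence of HRV. Passing tests therefore
demonstrate that the pipeline recovers the apneic HR/amplitude signature it
targets under controlled conditions — not clinical performance on real
overnight recordings, which depends on annotation noise and physiological
variability the synthetic cohorts do not contain. Accuracies on the
synthetic benchmark are accordingly higher than what real corpora yield.

## Benchmark problem sizes

The standard synthetic benchmark (`harness.reference_cohort_experiment`, and
`scripts/acceptance.py`) uses twenty 60-minute recordings — half apneic
(class B), half normal (class C); class A needs ≥ 100 apnea minutes and is
infeasible inside 60-minute recordings — with every third recording held
out, the CNN trained for up to 30 epochs, and all four baselines run on the
identical split. These sizes were chosen as the smallest cohort on which
recording-level splitting, AHI correlation across a meaningful severity
spread, and all five classifiers remain exercised end to end.

## Numerical notes and edge cases

* All randomness flows through `numpy.random.default_rng` seeded explicitly;
  identical seeds give bit-identical simulations, fold assignments, weight
  initializations and loss histories.
* The median filter compares each value against the median of the *original*
  neighbourhood (computed once per pass); it is idempotent on typical RR
  series and length-preserving always.
* Interpolation requires ≥ 4 support points overlapping the window (cubic
  requirement); the error names the offending minute. One support point
  beyond each window edge, when available, steadies the spline at the
  boundary.
* `layer_output_length` raises when the input is shorter than the kernel;
  pooling assumes kernel = stride (the only configuration used).
* Degenerate evaluation inputs (zero confusion denominators, single-class
  AUC, zero AHI variance) flag NaN or raise a named validation error rather
  than silently producing numbers.
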