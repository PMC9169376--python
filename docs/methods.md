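# Methods

This note documents the models, conventions and numerical choices behind
`lithowarn`, and what its synthetic benchmark does and does not show.

## Signal model and data contract

The observable is a single-channel acceleration-**magnitude** trace sampled
at 100 Hz (one sample per 10 ms), with a per-sample state label in
{0 = Idle, 1 = Stone, 2 = Tissue}. Per-sample labels are the canonical
representation (interval annotations are expanded on read), which makes the
purity of every analysis window checkable sample by sample. Files are CSV
(canonical) or XLSX with case-insensitive columns `t_ms, magnitude, label`;
the sampling rate is taken from an explicit argument, inferred from the
median `t_ms` spacing, or defaulted to 100 Hz, in that order. Round-trips
preserve labels exactly and magnitudes to ≤1e−9 relative.

## Synthetic shockwave simulator

Each state emits

s(t) = | n(t) + Σᵢ Aᵢ · exp(−(t−tᵢ)/τ) · cos(2π f (t−tᵢ)) |,

with n(t) white Gaussian noise of std σ, burst arrival times tᵢ a
homogeneous Poisson process of rate λ, and per-burst amplitudes
Aᵢ = A·(1 + 0.1·zᵢ), zᵢ ~ N(0,1). The damped cosine is the minimal model of
a vapor-bubble collapse transient: impulsive onset, exponential ring-down
at a dominant frequency. The absolute value reflects the logged quantity —
an acceleration magnitude is nonnegative. Overlapping bursts sum linearly
before rectification; burst envelopes are truncated after 8τ (residual
< 4·10⁻⁴ of the peak).

Default profiles (device units are arbitrary; Nyquist is 50 Hz):

| state  | σ    | λ (Hz) | A    | f (Hz) | τ (s) |
|--------|------|--------|------|--------|-------|
| Idle   | 0.05 | 0      | –    | –      | –     |
| Stone  | 0.05 | 40     | 1.5  | 35     | 0.04  |
| Tissue | 0.05 | 30     | 0.25 | 12     | 0.1   |

Rationale: clinical lithotripsy lasers pulse at tens of hertz during
activation, so transients arrive densely and overlap into a sustained
vibration — at a few bursts per second a 0.5 s window would often contain
no transient at all and be indistinguishable from Idle in principle. Stone
hits are strong, fast-decaying and higher-frequency (impulsive fracture),
tissue hits weak, slow and low-frequency (damped absorption), so the
classes differ in amplitude *and* spectral content, and the class-averaged
FFT magnitudes order Stone > Tissue > Idle across essentially the whole
0–50 Hz band (asserted at ≥80 % of bins). The 0.1 relative amplitude
jitter models pulse-to-pulse energy variability.

Seeding: the master seed spawns one independent substream per session
block (`SeedSequence(seed, spawn_key=(block,))`), so a block's content
depends only on its position. Within a block the draw order is fixed
(burst count, arrival times, amplitudes, noise), which makes the signal
exactly linear in (A, σ) for a given seed.

What the simulator does **not** emulate: real accelerometer transfer
functions and mount resonances, hand movement and instrument-handling
artifacts, drifting noise floors, label errors around button presses, and
non-Poisson pulse trains (real lasers fire periodically). Passing the
benchmark therefore demonstrates that the pipeline recovers a strong,
stationary class structure — not that it reaches any particular accuracy
on clinical recordings.

## Windowing and spectral analysis

Non-overlapping (tumbling) windows of 50 samples start at index 0; a
trailing remainder is dropped, and windows containing more than one label
are discarded rather than majority-labeled, so neither class spectra nor
training labels are contaminated and windows stay statistically
independent for cross-validation. The per-window spectrum is the unscaled
one-sided DFT magnitude |rfft(x)| (no detrend, no taper): 26 bins at
0, 2, …, 50 Hz, with Σ|X_k|² over the two-sided spectrum equal to T·Σx².
Class-average spectra are bin-wise arithmetic means; magnitudes are stored
linearly and should be plotted on a log axis.

## Discrete wavelet transform

Single level only. Analysis convolves with the decomposition low/high-pass
taps and keeps every other output; the feature vector is cA ∥ cD.
Embedded taps are the standard published filter banks (identical to
PyWavelets', which serves as the test-time reference): haar (2 taps),
db2 (4), db4 (8), rbio2.4 (10), dmey (62-tap FIR approximation of the
Meyer wavelet).

Boundary handling:

* `symmetric` (default) — half-sample symmetric extension by L−1 samples
  per side, repeating the reflection when L−1 exceeds the window (the dmey
  case at T=50); output length ⌊(T+L−1)/2⌋ per channel. Matches the
  reference library's `symmetric` mode to 1e−10. The default is applied
  uniformly so all five families are legal on 50-sample windows; the
  feature dimension then varies by family (50→110), which the forest
  tolerates.
* `none` — periodized (circular) convolution with downsampling phase L/2:
  no extension values are invented, output is exactly T/2 per channel
  ("half the original length"), and orthogonal families conserve energy.
  Requires even T ≥ L, so dmey is excluded at T=50 and asks for
  `symmetric` in its error message.

The dmey taps are only *approximately* orthogonal (‖dec_lo‖² ≈ 1.00224),
so its energy ratio carries an irreducible ≈ 2.2·10⁻³ bias and the
classical synthesis bank cannot reconstruct below ~10⁻² error.
`idwt_single_level` — needed only for verification — therefore inverts the
analysis operator directly: the per-(wavelet, length, mode) analysis
matrix is built by transforming unit vectors (cached) and the coefficients
are solved by least squares, which is exact to machine precision for every
family, dmey included. The forward transform, which is what the classifier
consumes, remains tap-for-tap identical to the reference library.

## Random forest

scikit-learn's `RandomForestClassifier` with its default hyperparameters —
100 trees, Gini impurity, √d features per split, bootstrap resampling,
trees grown to purity — behind a frozen config/contract surface.
`predict_proba` is the mean of per-tree leaf class-frequency vectors (soft
voting); `predict` is the argmax with ties broken toward the lowest class
code, which fixes confusion-matrix reproducibility. Training is
deterministic given (data, seed).

## Validation protocol

Per repetition r (of n): a fresh balanced subset of m segments per class
is drawn without replacement from substream r of the master seed; a
shuffled stratified k-fold split then trains a forest (its own seeded
substream) on k−1 folds and evaluates the held-out fold. Train and test
indices are disjoint by construction and asserted at run time. Defaults
m/n/k = 20/100/10; the protocol is bookkept as m·n·k = 20,000 data-subset
combinations, while the countable unit actually aggregated is the n·k
fold evaluation — the accuracy mean is over all n·k folds and the standard
deviation is reported both over folds and over the n repetition means,
labeled separately, since the two definitions differ and the conventional
choice is ambiguous.

Confusion matrices accumulate counts over all held-out predictions and are
row-normalized (rows = true class; zero-support rows are emitted as zeros
with a warning). ROC analysis is one-vs-rest for each of the three cases
(Idle vs Stone+Tissue, Stone vs Idle+Tissue, Tissue vs Idle+Stone): per
fold, the positive-class probability is thresholded at every distinct
score, the curve is anchored at (0,0), AUC is trapezoidal, and curves are
vertically averaged by linear interpolation onto a fixed 101-point FPR
grid with a per-point ±1 std band. The AUC equals the Mann-Whitney
U-statistic (verified against an independent pairwise-count oracle).

The dummy-data null re-runs the *identical* pipeline — raw uniform U(0,1)
segments (the same nonnegative range as magnitude traces), balanced
labels, DWT features, forest, repeated CV — and must score accuracy
statistically indistinguishable from 1/3 and AUCs ≈ 0.5. Dummy data are
injected as raw segments, not as feature vectors, so the feature transform
is part of what the null certifies.

## Streaming monitor

Windows of the training timestep are classified at stride `hop` (default =
window, one decision per 0.5 s) in arrival order with no lookahead; event
predictions are bitwise equal to batch predictions of the same windows.
No temporal smoothing is applied by default — windows are classified
independently — and each event carries its own wall-clock compute latency,
which is reported but never asserted against a threshold because it is
hardware-dependent (typically a few ms per decision on a desktop CPU).

## Problem sizes and tolerances

The shipped benchmark uses 60 s per state (120 windows per class) for
power runs and n = 20 repetitions for both the separable-data and
dummy-null configurations — large enough that the repetition-mean standard
error of the null accuracy is ≈ 0.02 while a full run stays under a minute
on one CPU; the full n = 100 study configuration is a config change.
Numerical gates: forward DWT vs reference 1e−8; reconstruction 1e−8;
orthogonal energy conservation 1e−6 relative (dmey documented at its true
≈ 2·10⁻³ bias); probability rows sum to 1 within 1e−9; round-trip
magnitudes 1e−9 relative. Chance-level checks use 3-standard-error gates
over the repetition distribution rather than fixed bands.

## Known limitations

* The simulator's stationarity and class separation are idealized;
  clinical accuracy claims require recorded surgical data.
* Only single-level DWT features are implemented (no wavelet packets or
  multi-level decompositions) and only the five families above.
* The forest uses library defaults throughout; no hyperparameter search,
  class weighting or calibration.
* Mixed-label windows are discarded, so state transitions themselves are
  never classified — the monitor's first clean decision after a change
  arrives up to one window late.
* Alerting policy (which states should trigger a warning, debouncing,
  feedback modality) is left to the caller.
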