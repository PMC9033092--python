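# Methods

## Signal model and cleaning procedure

The recorded channels are modelled as an instantaneous linear mixture
`X(t) = M s(t)` of statistically independent sources.  FastICA (log-cosh
contrast, symmetric decorrelation, tolerance 1e-4, at most 200 sweeps,
explicit seed) estimates the square model — `n_components = n_channels` by
default — after removing channel means, which are restored on every
reconstruction.  Because component order and sign are arbitrary and vary
between runs, every comparison in the package matches components to
references by maximal absolute correlation.

Two cleaning arms are implemented on top of one shared decomposition:

* **Component zeroing (baseline).**  The components most associated with
  artifact are set to zero and the channels remixed.  Ranking uses the
  absolute correlation with a supplied artifact reference when one exists
  (on synthetic data, the ground-truth artifact track), otherwise excess
  kurtosis (blink and burst transients are strongly super-Gaussian; an
  all-Gaussian decomposition, max excess kurtosis < 1, is flagged
  low-confidence).  The default removes the top 2 components, mirroring
  the common two-frontal-components practice.

* **wICA.**  Every component is decomposed with a multilevel Daubechies
  DWT (db4 by default) and hard-thresholded: coefficients whose magnitude
  exceeds `T = σ̂ √(2 ln N)` — `N` the component length — are zeroed, the
  retained coefficients reconstruct the neural part `l_i`, and the
  artifact part is `f_i = s_i − l_i`.  Note the inversion of classic
  wavelet denoising: the *large* coefficients are the artifact.  Cleaned
  channels are `M [l_1 … l_n]` plus the restored means.  A literal
  threshold variant `T = 2 ln(N) σ̂` is selectable
  (`variant="literal_2logN"`); it grows much faster with `N` and in
  practice zeroes almost nothing, which makes it useful mainly for
  pass-through checks.

### Noise-scale estimation (σ̂)

σ̂ is a robust median-absolute-deviation estimate, `median(|W|)/0.6745`,
of the wideband neural background.  The classic denoising recipe takes it
from the finest detail level only.  That recipe silently assumes the
background is white; band-limited EEG (0.1–40 Hz) has an essentially
empty finest band, so the finest-level estimate collapses to ~0, the
threshold with it, and hard thresholding then zeroes a third of all
coefficients and destroys the signal.  A single scale pooled over all
levels fails the same way (the empty levels drag the median down).  The
default is therefore **per-level** estimation: one MAD scale per
coefficient array, each plugged into the threshold formula with the full
segment length `N`.  This tracks the strongly level-dependent background
variance of band-limited signals while staying robust to the sparse
artifact outliers, and it restores the intended behaviour that a clean
component passes through nearly untouched.  `finest` and `global` remain
selectable for genuinely broadband data.

### Decomposition depth and transform details

The automatic depth is `floor(log2(fs))` levels (8 at 500 Hz, 7 at
250 Hz), pushing the approximation band below ~1 Hz so that slow,
high-energy ocular transients land in thresholdable levels; the
approximation coefficients participate in thresholding by default for the
same reason (switchable).  Transforms use periodized boundaries with the
signal zero-padded to a multiple of `2^levels`: on such lengths the
periodized DWT is exactly orthonormal, which is what guarantees both
perfect reconstruction (round-trip error < 1e-8) and that discarding
coefficients can never increase a component's energy.  (Without the
padding, the transform is slightly redundant on odd intermediate lengths
and the energy bound can be violated by a few parts in 10⁴.)

## Pre-filtering and edge handling

Fixed pre-filters follow common practice: a second-order IIR notch at
50 Hz (Q = 30) and a 4th-order Butterworth band-pass 0.1–40 Hz, both
applied forward–backward (zero phase).  The 0.1 Hz high-pass has a
multi-second impulse response; with short default padding its edge
transient is large enough that ICA isolates it as a spurious spiky
component.  Filtering therefore uses generous even-extension padding
(~3 periods of the low cutoff), and the pipeline discards
`filter_trim_s = 5` s from each end after filtering, simulating extra
tape so analysis windows keep their nominal duration.  Attenuation
figures: ≥ 30 dB at the notch frequency, ≥ 20 dB one octave outside the
pass-band, pass-band gain within 1%.

## Synthetic ground truth

The simulator emulates a high-density vigilance study: 62 channels at
500 Hz by default, square mixing, ≥ 10-minute sessions, with exact
bookkeeping `mixed = neural + artifact`.

* **Neural sources** — independent sums of band-passed Gaussian noise
  with relative band powers delta 1.0 / theta 0.8 / alpha 1.0 / beta 0.5
  (delta- and alpha-dominant resting-like spectrum), unit RMS scaled to
  10 µV.  Empirical band powers match the configuration within 10% at
  300 s.
* **Blink sources** (2) — positive 300 ms raised-cosine pulses, Poisson
  events at 6/min, peak 10× neural RMS, mixed through a frontally
  decaying column (the first quartile of channels is "frontal").
* **Muscle sources** (2) — 500 ms Hann-windowed bursts of >20 Hz noise,
  2/min, 5× neural RMS.
* **Line source** — 50 Hz sinusoid, 2 µV.
* **Sensor noise** — 1 µV white noise per channel, counted on the
  artifact track.  This term matters: with a noiseless square mixture,
  FastICA separation is essentially perfect and *no cerebral activity
  leaks into artifact components*, which removes the very phenomenon wICA
  exists to fix.  A 10% noise floor yields realistic, imperfect unmixing.

The two-state generator shares the mixing matrix bitwise between states
and scales theta and alpha source power by `1 + state_shift` (absolutely;
other bands untouched) in the decrement segment.  Event times, mixing
and noise all derive from two explicit seeds; identical configurations
are bitwise reproducible.

What the simulator does **not** model: volume-conduction head geometry,
non-stationary neural rhythms (sources are stationary band-limited
noise), cardiac artifacts, electrode drift or pops.  Passing tests
therefore demonstrate the algorithmic claims under a controlled linear
mixing model, not clinical performance on real EEG.

## Features and classification

Band power is the integral (sum × bin width) of a Hann-tapered
periodogram over half-open band intervals, computed per channel on
2-second windows hopped by 1 s — 299 epochs per 5-minute window.  The
alert and decrement windows supply class labels 0/1.  Classifiers use
fixed, conventional hyperparameters (KNN k=5 Euclidean; linear
discriminant analysis; Gaussian Naive Bayes; CART with seeded tie-breaks;
RBF-SVM C=1, gamma scaled); features are standardized per fold on
training data only; folds are stratified, shuffled with an explicit seed,
and every epoch is tested exactly once.  Sensitivity is the recall of the
decrement class, specificity that of the alert class; reports give
mean ± sd over folds in percent.

A protocol caveat the synthetic data makes visible: with epochs drawn
from one recording per state, the finite-segment band-power offset
between the two specific noise realizations is learnable within-recording
even when the states are statistically identical, biasing null accuracy a
few points above 50%.  The effect shrinks as `sqrt(window/segment)`; the
null-calibration check therefore uses 600 s segments, where the best
classifier stays within 44–60% across seeds, while effect-driven checks
run at the protocol's 300 s.

## Head-to-head comparison protocol

`compare_cleaning_methods` draws independent recordings (fresh mixing and
noise per replicate), pre-filters and trims, fits one FastICA per
recording, and scores both arms against the identically filtered true
neural mixture: mean per-channel correlation, RMSE, residual artifact
power fraction, and per-band PSD distortion.  At the desk scale used in
tests — 16 channels, 250 Hz, 300 s, default artifact mix with 10×-RMS
blinks, 20 replicates — wICA wins the correlation comparison in 16/20
replicates and roughly quarters the delta-band PSD distortion.  On
shorter segments (≤ 2 min) the comparison degrades toward a coin flip:
the universal threshold sits lower relative to the background maximum,
and the top-2 baseline sometimes removes exactly the two blink
components, which on clean synthetic mixtures is nearly optimal.  Win
rates at other seeds fluctuate around ~70–80%.

## Known limitations

* The square-model reconstruction identity holds to 1e-6 only when
  `n_components = n_channels`; reduced models reconstruct approximately.
* Artifact-component ranking against a ground-truth reference is an
  oracle available only for synthetic data; the kurtosis fallback is a
  stand-in for the visual inspection used in practice and is flagged
  low-confidence on near-Gaussian decompositions.
* EDF files are read (via MNE) but not written; the native on-disk format
  is delimited text with a JSON sidecar.
* Thresholding all components inevitably clips the extreme tail of
  genuinely neural components; at protocol-length segments this costs
  < 1% of channel variance, but it grows on short segments.
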