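# wicaeeg

Wavelet-enhanced ICA (wICA) artifact removal for multichannel EEG, with the
full downstream vigilance-assessment chain — band-power features and
two-state classification — validated end to end on synthetic recordings
with exact ground truth.

## The problem

EEG recorded during sustained-attention tasks is contaminated by eye
blinks, muscle bursts, mains interference and sensor noise.  The standard
remedy decomposes the channels with Independent Component Analysis,

```
X(t) = M s(t),
```

identifies the artifact components, sets them to zero, and remixes
(`X̂ = M ŝ`).  Zeroing whole components, however, also discards whatever
cerebral activity leaked into them.  wICA instead splits every independent
component into a high-amplitude artifact part `f(t)` and a low-amplitude
neural part `l(t)`,

```
s_i(t) = f_i(t) + l_i(t),
```

by hard-thresholding its Daubechies wavelet coefficients at the universal
threshold `T = σ̂ √(2 ln N)` (large coefficients carry the localized,
high-power artifact; they are zeroed and the remainder reconstructs
`l_i`).  The cleaned channels are remixed from the neural parts only:

```
X̂(t) = M [l_1, …, l_n](t).
```

Downstream, vigilance is assessed by integrating the per-channel power
spectral density over the delta (0.1–4 Hz), theta (4–8 Hz), alpha
(8–13 Hz) and beta (13–30 Hz) bands on 2-second moving windows, labelling
the first five minutes of a session *alert* and the last five *vigilance
decrement*, and classifying epochs with KNN, Discriminant Analysis, Naive
Bayes, Decision Tree and an RBF-SVM under randomized stratified 10-fold
cross-validation.

Because real task EEG is rarely shareable, the package ships a first-class
simulator (`wicaeeg.synthgen`) producing recordings in which the neural
and artifact mixtures are known exactly (`mixed = neural + artifact`
sample for sample), so every stage — and the wICA-vs-ICA comparison
itself — can be scored against ground truth.

## Worked example

```python
import numpy as np
from wicaeeg import (SimulationConfig, simulate_eeg, notch_filter, bandpass_filter,
                     trim_edges, fastica_decompose, rank_artifact_components,
                     ica_zero_clean, wica_clean, score_removal)

cfg = SimulationConfig(n_channels=16, fs=250.0, duration=310.0,
                       blink_amplitude=10.0, mixing_seed=7, noise_seed=7)
truth = simulate_eeg(cfg)

def prep(rec):  # 50 Hz notch, 0.1-40 Hz band-pass, drop filter edges
    return trim_edges(bandpass_filter(notch_filter(rec, 50.0), 0.1, 40.0), 5.0)

mixed, neural, artifact = prep(truth.mixed), prep(truth.neural), prep(truth.artifact)

dec = fastica_decompose(mixed, seed=7)
ranking = rank_artifact_components(dec, reference=artifact)
baseline = ica_zero_clean(dec, ranking.order[:2])   # conventional: zero top-2 ICs
result = wica_clean(mixed, decomposition=dec)       # wICA: threshold every IC

for name, cleaned in [("wICA", result.cleaned), ("ICA top-2 zeroing", baseline)]:
    m = score_removal(cleaned, truth, name, neural_reference=neural,
                      artifact_reference=artifact)
    print(f"{name:18s} corr={m.corr_to_neural:.3f}  rmse={m.rmse_to_neural:.2f} uV  "
          f"delta-PSD distortion={m.band_psd_distortion['delta']:.3f}")
```

prints

```
wICA               corr=0.978  rmse=1.61 uV  delta-PSD distortion=0.097
ICA top-2 zeroing  corr=0.962  rmse=2.28 uV  delta-PSD distortion=0.146
```

`corr` is the mean per-channel Pearson correlation between the cleaned
channels and the true (filtered) neural mixture; `rmse` is in microvolts;
the delta-PSD distortion is the relative error of the cleaned delta-band
power against the true neural spectrum.  Here wICA both tracks the neural
signal more closely and distorts its low-frequency power less than the
conventional component-zeroing baseline, because the sub-threshold part of
the blink components — leaked cerebral activity — is retained rather than
discarded.

## Command line

```sh
wica-pipeline simulate --config sim.yaml --out data/ --seed 7
wica-pipeline clean    --in data/mixed.tsv --out clean.tsv --notch 50 --band 0.1 40
wica-pipeline wica     --in clean.tsv --out wica.tsv --wavelet db4 --levels auto --seed 7
wica-pipeline run      --config run.yaml --out results/run1
```

`run` drives the whole chain (simulate → filter → ICA/wICA → band-power
features → cross-validated classification) for a cohort of simulated
subjects from one YAML config and writes per-subject and aggregate report
tables; re-running an identical config reproduces every table bitwise.

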