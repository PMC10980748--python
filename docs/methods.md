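# Methods

This note documents the models, parameter choices and numerical
decisions behind `neuroalign`, and what the synthetic benchmarks do and
do not establish.

## Analysis model

### Brain embeddings

Raw voltage (electrodes × samples, fixed sampling rate, 512 Hz
throughout the examples) passes through a fixed chain:

1. **Despiking.** Per electrode, samples outside
   `median ± k·IQR` (`k = 4`) are replaced by cubic interpolation
   through the retained samples. The scale reading — an IQR multiple
   around the median — is the only interpretation of a "quartiles above
   the median" rule that defines a scale; `k` is configurable. On
   Gaussian signal the false-positive rate of this threshold is
   negligible (≈ 5.4 σ).
2. **Common average referencing.** The instantaneous across-electrode
   mean is subtracted; requires ≥ 2 electrodes.
3. **HFBB power.** Morlet wavelets with 6 cycles at centers every 5 Hz
   across 70–200 Hz; centers within 5 Hz of 60/120/180 Hz are dropped
   (21 centers remain). Linear power is averaged across centers, then
   log-transformed, then z-scored per electrode over the full recording
   (in that order: power → mean → log → z). Center spacing and the
   exclusion half-width are free choices set comparable to the wavelet
   bandwidth.
4. **Smoothing.** A unit-sum 50-ms Hamming kernel applied forward and
   backward (zero net phase), reflect padding. Note that smoothing after
   z-scoring slightly reduces the per-electrode SD below 1; the chain
   order is fixed as stated.
5. **Epoching.** At each lag on the grid (−4000…+4000 ms, 25-ms steps,
   321 lags) the window mean of `floor(window_ms·fs/1000)` samples
   (102 at 512 Hz for 200 ms) **centered** at onset + lag, one row per
   word event. Events whose window leaves the recording at any lag are
   dropped with a warning. A coarser grid is configurable; the window
   and the step are independent parameters.

### Zero-shot folds

One occurrence per word type is chosen uniformly at random
(seed-controlled; re-drawn per analysis unless the caller fixes the
selection). The onset-sorted selections are split into `k = 10`
contiguous blocks differing in size by at most one (remainders go to the
earliest folds, which keeps blocks contiguous and the rule unambiguous).
Since each type contributes exactly one event, train/test type
disjointness holds by construction and is still re-asserted on every
analysis run. The shuffle control draws a **derangement** of the
test-fold rows — every word gets a mismatching embedding — because a
plain permutation of a 110-word fold leaves on average one word paired
with its own embedding and inflates the chance level by ≈ 1/110; a plain
permutation remains available (`derange=False`). Ten random shuffles are
averaged per fold (the exact count is a free parameter).

### Encoding

Per lag × fold, OLS with intercept from the reduced embeddings to the
electrode matrix; the fit must be full rank (an underdetermined or
collinear design raises). Per held-out word, Pearson r between the
predicted and observed electrode vector — the correlation runs **across
electrodes** for each word, so ≥ 2 electrodes are required and words
with zero-variance observed patterns are dropped and logged.
The nearest-neighbor control substitutes each test embedding with the
most cosine-similar **training** embedding, computed in the reduced
space the model sees; ties break to the earliest training word. A less
conservative variant drawing the neighbor from the other test words is
available (`nearest_from_test=True`). No regularization by default;
ridge sits behind a flag.

### Decoding

Inputs are ten 62.5-ms bin means per electrode spanning 625 ms centered
at onset + lag (alignment is configurable; centered is the default).
The decoder is a compact convolutional regression network: 1-D
convolution over the bins (electrodes as input channels; 32 channels,
kernel 3) → ReLU → flatten → dense 128 → ReLU → dropout 0.2 → dense
output, minimizing MSE with Adam (learning rate 2·10⁻³, batch 32),
early-stopped when the development fold's MSE fails to improve for 10
consecutive epochs (cap 150). This is the smallest architecture
honoring "convolutional network + MSE + early stopping"; every knob is
exposed in `DecoderConfig`/`NetConfig`. It is implemented directly in
NumPy with one seeded generator, so training is bit-reproducible for a
fixed seed. Fold roles per evaluation: the test fold, the next fold
(cyclically) as development set, the remaining eight for training.

Classification is cosine similarity of each predicted embedding with
the candidate embeddings, softmax (temperature 1) over candidates,
probabilities averaged across the six ensemble members, and a
one-vs-rest ROC-AUC per label (one positive, the remaining test words
as negatives). The candidate set defaults to the **test fold**; a
dataset-wide candidate mode exists (`candidate_scope="dataset"`) since
both readings of the evaluation strategy are defensible. The linear
decoding variant maps the single-window brain embedding to the
embedding space by least squares (minimum-norm solution, since
electrode regressors may be collinear on noiseless synthetic data) with
no development fold.

### Inference

* Per-lag bootstrap of the mean per-word correlation (5000 resamples,
  one-sided against a positive mean, `(x+1)/(n+1)` continuity so p > 0),
  Benjamini–Hochberg FDR across lags at q = 0.01.
* Paired sign-flip permutation across words for variant/region
  contrasts (one-sided by default, matching the figure conventions;
  two-sided behind a flag). Region contrasts pair words at matched lags.
* Paired t with Bonferroni correction over the lag count.

## Synthetic data: what it emulates, and what it does not

The generator produces (i) a token stream with Zipf-weighted type
frequencies (exponent 1.1 by default), onsets as uniform order
statistics with a 100-ms minimum gap; (ii) per-occurrence embeddings:
each type has a random unit base vector and each occurrence is the base
rotated by an angle uniform in [0, cone angle] (default 20°) in a random
orthogonal direction — the "narrow cone" geometry of contextual
embeddings, with the 0° limit recovering a static embedding; (iii) raw
voltage whose 70–200 Hz amplitude envelope is
`baseline + kernel(t − onset)·(W·embedding)`, with a Gaussian response
kernel (unit peak at +200 ms, SD 150 ms, optional pre-onset Gaussian at
−500 ms), white noise, 60/120/180 Hz line sinusoids and impulsive
artifact spikes whose indices are recorded for despike testing.

**Carrier choice.** The default carrier is a single sinusoid per
electrode at a random in-band frequency (stratified across electrodes
so that no two carriers beat through the common average reference),
giving a deterministic envelope that the wavelet average tracks
exactly. A sum-of-sinusoids carrier (`carrier="multitone"`) is closer
to broadband neural power but its envelope carries Rayleigh-like fading
that acts as irreducible multiplicative noise (~25 % relative SD after
center and window averaging), which buries small word responses; it is
kept for stress-testing, not for recovery benchmarks.

The generator does **not** model 1/f spectra, cortical anatomy, speech
acoustics, or any realistic noise covariance. Passing benchmarks on it
therefore demonstrates that the pipeline's *machinery* is correct
(shapes, alignment, leakage-freedom, statistical calibration, exact
recovery under its own generative assumptions) — not that real cortical
recordings would yield any particular effect size.

An analytic shortcut (`oracle_brain_embeddings`, `oracle_decoder_input`)
evaluates `kernel(lag)·(X Wᵀ)` directly, bypassing signal synthesis;
the signal-level and oracle routes are compared end to end in the test
suite. Because per-electrode z-scoring applies an arbitrary affine gauge
per electrode, pipeline-vs-oracle pattern correlations are computed
after standardizing each electrode across words in both matrices.

## Benchmark problem sizes

Chosen as desk-scale configurations the package commits to:

* encoding recovery: 1100 types, 81 electrodes, 50 dimensions,
  noiseless oracle responses at the kernel peak (mean zero-shot r
  > 0.95; shuffle control CI covers 0; nearest < actual);
* decoding calibration: same scale, oracle-binned input with noise SD
  0.05, six members; evaluated on a subset of test folds (the AUC is
  fold-wise i.i.d., so a subset estimates the fold average unbiasedly);
* type-I calibration: 50 replicate null pipelines (150 types, 20
  electrodes, 12 dimensions, 20 lags, 500 bootstrap draws) with
  globally mismatched embeddings; FDR-significant fraction ≤ q within
  three binomial SEs;
* signal-level recovery: 60 types, 16 electrodes, 220-s recording,
  noiseless (gauge-aligned pattern r > 0.9 at the kernel peak).

## Known limitations

* The symbolic feature inventory ships with package defaults (a coarse
  11-tag POS set with a heuristic fallback tagger, the scikit-learn
  English stopword list, 16 case/digit/punctuation shape classes, 19
  prefixes, 28 suffixes); group cardinalities are enforced, contents
  are user-overridable via TOML. Supplied POS columns always take
  precedence over the heuristic tagger.
* PCA fit scope defaults to all rows ("global"); pass the training rows
  of the current split for a leakage-safe reduction. Tables carry
  provenance (fold isolation, context inclusion) but the pipeline does
  not yet refuse mixed-provenance combinations automatically.
* The decoder is CPU-only NumPy; large ensembles over the full 321-lag
  grid are not practical — the intended use is one lag (or a coarse
  grid) at a time.
* Bootstrap p-values are bounded below by 1/(n_boot+1); with the
  default FDR level and 321 lags, n_boot ≥ 5000 is needed for the
  smallest BH thresholds to be reachable.
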