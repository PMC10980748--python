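# neuroalign

Zero-shot alignment of multielectrode **brain embeddings** with
**contextual word embeddings**, end to end on synthetic data with known
ground truth.

## The scientific problem

When a listener hears continuous natural speech, the population activity
across intracranial electrodes in a language area can be read out as one
vector per word — a *brain embedding*, with electrodes as dimensions.
Deep language models likewise assign each word occurrence a *contextual
embedding*. The question this package operationalizes: do the two vector
spaces share **common geometric patterns**, precise enough that a linear
map learned on one set of word types predicts the representation of word
types it has never seen?

The analysis is *zero-shot*: one occurrence of each unique word type is
selected, the types are split into `k = 10` folds **contiguous in
stimulus time** with no type shared between folds, and a per-lag map is
fit on 9 folds and evaluated on the held-out fold. Because no test word
type is ever seen in training, above-chance performance can only come
from shared geometry, not memorization. Two controls sharpen the claim:

* **nearest-neighbor control** — each test embedding is replaced by its
  most cosine-similar *training* embedding; if predictions beat this, the
  mapping interpolates more precisely than any memorized word;
* **shuffle control** — test words are matched with mismatching
  embeddings (a derangement); performance must collapse to chance.

### Core model

Preprocessing converts raw voltage to high-frequency-broadband power
(70–200 Hz, "HFBB"): despiking (samples beyond median ± 4·IQR imputed by
cubic interpolation), common average referencing, six-cycle Morlet
wavelet power averaged over centers that avoid 60/120/180 Hz line noise,
log-transform, per-electrode z-scoring, and zero-phase 50-ms Hamming
smoothing. At each lag `t ∈ [−4000, 4000]` ms (25-ms steps) the brain
embedding `Y ∈ R^{words × electrodes}` averages a 200-ms window (102
samples at 512 Hz) centered at onset + `t`.

**Encoding** fits, per lag and fold, OLS with intercept
`Y ≈ [1, X] B` from the 50-dimensional (PCA-reduced) embeddings `X`, and
scores each held-out word by the Pearson correlation between predicted
and observed electrode patterns.

**Decoding** reverses the direction: the signal is averaged in ten
62.5-ms bins (32 samples each) spanning 625 ms, a small convolutional
regression network (trained under MSE with dev-fold early stopping; 8
train / 1 dev / 1 test folds) predicts the embedding, and a six-member
ensemble classifies each test word by cosine similarity → softmax over
the test-fold candidates → per-label one-vs-rest ROC-AUC (0.5 chance,
1 perfect).

**Inference**: word-level bootstrap (5000 resamples) per lag with
Benjamini–Hochberg FDR at q = 0.01; paired sign-flip permutation tests
for variant contrasts; paired t with Bonferroni for region contrasts.

The synthetic generator supplies every input with known ground truth:
Zipf-weighted token streams, per-occurrence embeddings lying in a narrow
cone per word type, and raw carriers whose 70–200 Hz amplitude envelope
encodes `W·embedding` through a Gaussian response kernel peaking 200 ms
after word onset (plus optional pre-onset component, noise, line noise
and artifact spikes).

## Worked example

```python
import numpy as np
from neuroalign import synthetic, folds
from neuroalign.encoding import ZeroShotEncodingModel

stream = synthetic.generate_stream(n_types=200, n_tokens=500,
                                   duration_s=400.0, seed=1)
table = synthetic.generate_contextual_table(stream, embed_dim=50,
                                            cone_angle_deg=20.0, seed=2)
rng = np.random.default_rng(3)
gt = synthetic.GroundTruth(map_matrix=rng.standard_normal((81, 50)) / np.sqrt(50))

sel = folds.select_unique_instances(stream, seed=4)
spec = folds.make_folds(sel, k=10)
tab = table.take(sel["event_idx"].to_numpy())
brain = synthetic.oracle_brain_embeddings(spec, tab, gt, [0.0, 100.0, 200.0, 300.0])

res = ZeroShotEncodingModel(tab, brain, spec).fit(
    variants=("actual", "nearest", "shuffled"), seed=0)
print(res.lag_summary().round(3))
```

prints (noiseless ground truth, so the actual variant is exact):

```
    lag_ms   variant  mean_r    n     se
0      0.0    actual   1.000  200  0.000
1      0.0   nearest   0.353  200  0.008
2      0.0  shuffled  -0.003  200  0.005
...
```

`mean_r = 1.0` for the actual variant says held-out brain embeddings are
perfectly interpolated from embedding geometry alone; the nearest-
neighbor control is far lower (the mapping is more precise than
memorization), and the shuffle control sits at zero. A full pipeline run
from raw synthetic voltage is one command:

```bash
neuroalign run --config run.toml --out runs/demo
neuroalign report runs/demo
```

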