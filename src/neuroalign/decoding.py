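"""Zero-shot decoding: brain activity -> embedding -> word classification.

The decoder maps the binned neural signal of each word (ten 62.5-ms bins
per electrode spanning 625 ms around the analysis lag) to the word's
contextual embedding with a small convolutional regression network
trained under MSE with early stopping (8 training folds, 1 development
fold, 1 test fold).  Six independently initialized members form an
ensemble.  Classification is two-step: cosine similarity between each
predicted embedding and the candidate embeddings, softmax over
candidates, probabilities averaged across ensemble members, and a
one-vs-rest ROC-AUC per label (one positive, the other test words as
negatives); 0.5 is chance, 1 is perfect classification.

A linear variant (:func:`linear_decode_variant`) runs OLS from a single
200-ms brain embedding instead of the network, mirroring the encoding
analysis in reverse.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._nn import ConvRegressor, NetConfig
from .encoding import fit_ols, predict as ols_predict
from .folds import FoldSpec

logger = logging.getLogger(__name__)

__all__ = [
    "DecoderConfig",
    "DecodingResults",
    "ZeroShotDecodingModel",
    "bin_signal",
    "train_decoder",
    "ensemble_predict",
    "classify_and_auc",
    "linear_decode_variant",
]


@dataclass
class DecoderConfig:
    """Decoder architecture, optimization and ensemble settings."""

    net: NetConfig = field(default_factory=NetConfig)
    ensemble_size: int = 6
    candidate_scope: str = "test_fold"  # "test_fold" | "dataset"

    def __post_init__(self) -> None:
        if self.ensemble_size < 1:
            raise ValueError("ensemble_size must be >= 1")
        if self.candidate_scope not in ("test_fold", "dataset"):
            raise ValueError("candidate_scope must be 'test_fold' or 'dataset'")


def bin_signal(
    sig,
    events: pd.DataFrame,
    lag_ms: float,
    n_bins: int = 10,
    bin_ms: float = 62.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Average the signal in consecutive bins around each event.

    The ``n_bins * bin_ms`` span (625 ms by default) is centered at
    ``onset + lag_ms``; each bin averages ``round(bin_ms * fs / 1000)``
    samples (32 at 512 Hz).  Out-of-range events are dropped with a
    warning.  Returns ``(tensor words x electrodes x n_bins,
    kept_event_indices)``.
    """
    import warnings

    n_bin_samp = int(round(bin_ms * sig.fs_hz / 1000.0))
    total = n_bin_samp * n_bins
    onsets = np.asarray(events["onset_s"], dtype=float)
    centers = np.round((onsets + lag_ms / 1000.0) * sig.fs_hz).astype(int)
    starts = centers - total // 2
    valid = (starts >= 0) & (starts + total <= sig.n_samples)
    if (~valid).any():
        warnings.warn(
            f"bin_signal: dropped {int((~valid).sum())} out-of-range events",
            stacklevel=2,
        )
    keep = np.flatnonzero(valid)
    tensor = np.empty((len(keep), sig.n_electrodes, n_bins))
    for i, s in enumerate(starts[keep]):
        win = sig.power[:, s : s + total]
        tensor[i] = win.reshape(sig.n_electrodes, n_bins, n_bin_samp).mean(axis=2)
    return tensor, keep


@dataclass
class Decoder:
    """A trained network plus the train-set input standardization."""

    net: ConvRegressor
    mean: np.ndarray
    sd: np.ndarray
    history: dict

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.net.predict((x - self.mean) / self.sd)


def train_decoder(
    tensor: np.ndarray,
    targets: np.ndarray,
    train_idx,
    dev_idx,
    config: DecoderConfig | None = None,
    seed: int = 0,
) -> Decoder:
    """Train one decoder member on the training folds with early stopping.

    Inputs are standardized per feature using training-set statistics.
    Deterministic for a fixed seed and configuration; raises on a
    non-finite loss.
    """
    if config is None:
        config = DecoderConfig()
    train_idx = np.asarray(train_idx)
    dev_idx = np.asarray(dev_idx)
    if np.intersect1d(train_idx, dev_idx).size:
        raise ValueError("train and dev folds overlap")
    x, y = np.asarray(tensor, float), np.asarray(targets, float)
    mean = x[train_idx].mean(axis=0, keepdims=True)
    sd = x[train_idx].std(axis=0, keepdims=True)
    sd[sd == 0] = 1.0
    net = ConvRegressor(
        n_channels=x.shape[1],
        n_bins=x.shape[2],
        n_out=y.shape[1],
        config=config.net,
        seed=seed,
    )
    xs = (x - mean) / sd
    history = net.fit(xs[train_idx], y[train_idx], xs[dev_idx], y[dev_idx])
    return Decoder(net=net, mean=mean, sd=sd, history=history)


def ensemble_predict(decoders, tensor: np.ndarray) -> np.ndarray:
    """Stack per-member predictions, (members x words x dim); no averaging."""
    return np.stack([d.predict(tensor) for d in decoders])


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def classify_and_auc(
    member_preds: np.ndarray,
    candidates: np.ndarray,
    true_label: np.ndarray | None = None,
    temperature: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Cosine-softmax classification and per-label one-vs-rest ROC-AUC.

    Per member: cosine similarity of each predicted embedding with every
    candidate embedding, softmax over candidates.  The member
    probabilities are averaged, and for each label the ROC-AUC of its
    probability column against the true-word indicator (one positive,
    the rest negatives) is computed.  Returns ``(mean_auc,
    per_label_auc)``.

    ``true_label[i]`` is the candidate index of test word i (identity by
    default); zero-norm predictions get uniform probabilities.
    """
    from sklearn.metrics import roc_auc_score

    P = np.asarray(member_preds, dtype=float)
    if P.ndim == 2:
        P = P[np.newaxis]
    C = np.asarray(candidates, dtype=float)
    n_test = P.shape[1]
    n_cand = C.shape[0]
    if true_label is None:
        if n_test != n_cand:
            raise ValueError("need true_label when candidates differ from test words")
        true_label = np.arange(n_test)
    true_label = np.asarray(true_label)

    cn = np.linalg.norm(C, axis=1)
    if (cn == 0).any():
        raise ValueError("zero-norm candidate embedding")
    Cn = C / cn[:, None]
    probs = np.zeros((n_test, n_cand))
    for m in range(P.shape[0]):
        pred = P[m]
        pn = np.linalg.norm(pred, axis=1)
        zero = pn == 0
        if zero.any():
            logger.warning(
                "classify_and_auc: %d zero-norm predictions -> uniform", zero.sum()
            )
        pn[zero] = 1.0
        sim = (pred / pn[:, None]) @ Cn.T
        pm = _softmax(sim / temperature)
        pm[zero] = 1.0 / n_cand
        probs += pm
    probs /= P.shape[0]

    labels = np.unique(true_label)
    per_label = np.empty(len(labels))
    for i, lab in enumerate(labels):
        y = (true_label == lab).astype(int)
        per_label[i] = roc_auc_score(y, probs[:, lab])
    return float(per_label.mean()), per_label


def _fold_roles(k: int, test_fold: int) -> tuple[int, int]:
    """Development fold = the fold after the test fold (cyclically)."""
    return test_fold, (test_fold + 1) % k


def linear_decode_variant(
    brain: np.ndarray,
    targets: np.ndarray,
    folds: FoldSpec,
    shuffle_seed: int | None = None,
) -> "DecodingResults":
    """OLS brain-embedding -> word-embedding, then cosine-softmax AUC.

    No development fold (9 train / 1 test); mirrors the encoding analysis
    in the decoding direction.  ``shuffle_seed`` activates the
    label-shuffle control.
    """
    folds.assert_zero_shot()
    rng = np.random.default_rng(shuffle_seed) if shuffle_seed is not None else None
    rows = []
    for f in range(folds.k):
        tr, te = folds.train_mask(f), folds.test_mask(f)
        lin = fit_ols(brain[tr], targets[tr], allow_singular=True)
        preds = ols_predict(lin, brain[te])
        cands = targets[te]
        lab = np.arange(cands.shape[0])
        if rng is not None:
            lab = rng.permutation(lab)
        mean_auc, per_label = classify_and_auc(preds, cands, true_label=lab)
        for j, auc in enumerate(per_label):
            rows.append((np.nan, f, j, auc, "shuffled" if rng is not None else "actual"))
    df = pd.DataFrame(rows, columns=["lag_ms", "fold", "label", "auc", "variant"])
    return DecodingResults(scores=df, model="linear")


@dataclass
class DecodingResults:
    """Per-label ROC-AUC across folds (and lags) with summaries."""

    scores: pd.DataFrame  # columns lag_ms, fold, label, auc, variant
    model: str = "conv-ensemble"
    histories: list = field(default_factory=list)

    def mean_auc(self, variant: str = "actual") -> float:
        return float(self.scores[self.scores["variant"] == variant]["auc"].mean())

    def fold_summary(self) -> pd.DataFrame:
        g = self.scores.groupby(["variant", "fold"])["auc"]
        return g.agg(mean_auc="mean", n="count").reset_index()

    def summary(self) -> str:
        lines = [
            "Zero-shot decoding results",
            f"  model: {self.model}",
            f"  folds: {self.scores['fold'].nunique()}   "
            f"labels: {self.scores['label'].nunique()}",
            "",
            f"{'variant':>9} {'fold':>5} {'mean_auc':>9} {'n':>6}",
        ]
        for _, row in self.fold_summary().iterrows():
            lines.append(
                f"{row['variant']:>9} {int(row['fold']):>5d} "
                f"{row['mean_auc']:>9.4f} {int(row['n']):>6d}"
            )
        overall = " ".join(
            f"{v}={self.mean_auc(v):.4f}"
            for v in sorted(self.scores["variant"].unique())
        )
        lines += ["", f"overall mean ROC-AUC: {overall}"]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.scores.to_csv(path, sep="\t", index=False)


class ZeroShotDecodingModel:
    """Ensemble decoding model over one binned-input tensor.

    Parameters
    ----------
    tensor : ndarray, words x electrodes x n_bins
        Binned neural input aligned to ``folds.events`` rows (see
        :func:`bin_signal` or the synthetic oracle).
    targets : ndarray, words x dim
        Embedding targets, same row order.
    folds : FoldSpec
    config : DecoderConfig
    """

    def __init__(self, tensor, targets, folds: FoldSpec,
                 config: DecoderConfig | None = None):
        self.tensor = np.asarray(tensor, dtype=float)
        self.targets = np.asarray(targets, dtype=float)
        self.folds = folds
        self.config = config or DecoderConfig()
        if self.tensor.shape[0] != folds.n_words:
            raise ValueError("tensor rows must align with fold events")
        if self.targets.shape[0] != folds.n_words:
            raise ValueError("targets rows must align with fold events")

    def fit(
        self,
        seed: int = 0,
        test_folds=None,
        variants=("actual",),
        n_label_shuffles: int = 1,
    ) -> DecodingResults:
        """Train the ensemble per test fold and score both variants.

        For each test fold the next fold (cyclically) is the development
        set and the remaining folds train the members.  The "shuffled"
        variant reuses the trained members and permutes the word-to-
        embedding assignment in the test fold.
        """
        self.folds.assert_zero_shot()
        rng = np.random.default_rng(seed)
        if test_folds is None:
            test_folds = range(self.folds.k)
        rows = []
        histories = []
        for f in test_folds:
            te_f, dev_f = _fold_roles(self.folds.k, f)
            te = self.folds.test_mask(te_f)
            dev = self.folds.test_mask(dev_f)
            tr = ~(te | dev)
            members = [
                train_decoder(
                    self.tensor,
                    self.targets,
                    np.flatnonzero(tr),
                    np.flatnonzero(dev),
                    config=self.config,
                    seed=int(rng.integers(2**31)),
                )
                for _ in range(self.config.ensemble_size)
            ]
            histories.extend(m.history for m in members)
            preds = ensemble_predict(members, self.tensor[te])
            if self.config.candidate_scope == "test_fold":
                cands = self.targets[te]
                lab = np.arange(cands.shape[0])
            else:
                cands = self.targets
                lab = np.flatnonzero(te)
            if "actual" in variants:
                _, per_label = classify_and_auc(preds, cands, true_label=lab)
                for j, auc in enumerate(per_label):
                    rows.append((f, j, auc, "actual"))
            if "shuffled" in variants:
                acc = np.zeros(len(np.unique(lab)))
                for _ in range(n_label_shuffles):
                    perm = rng.permutation(lab)
                    _, per_label = classify_and_auc(preds, cands, true_label=perm)
                    acc += per_label
                for j, auc in enumerate(acc / n_label_shuffles):
                    rows.append((f, j, auc, "shuffled"))
        df = pd.DataFrame(rows, columns=["fold", "label", "auc", "variant"])
        df.insert(0, "lag_ms", np.nan)
        return DecodingResults(scores=df, model="conv-ensemble", histories=histories)
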