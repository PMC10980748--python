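"""Zero-shot encoding: per-lag OLS from word embeddings to electrode patterns.

For every lag and cross-validation fold an ordinary-least-squares map
(with intercept) is fit from the training words' embeddings to their
brain embeddings, then evaluated on held-out words the model never saw:
for each test word the Pearson correlation between the predicted and
observed electrode pattern is computed (across electrodes), and
correlations are pooled over test words and folds.

Two controls probe whether performance reflects shared geometry rather
than memorization: the *nearest* variant replaces each test embedding
with its most cosine-similar training embedding, and the *shuffled*
variant randomly mismatches test words and embeddings.

The module exposes both the operation-level functions (:func:`fit_ols`,
:func:`score_zero_shot`, :func:`nearest_train_control`,
:func:`run_encoding`) and a model/results pair
(:class:`ZeroShotEncodingModel` / :class:`EncodingResults`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .folds import FoldSpec, shuffle_assignment
from .stats import SignificanceResult, bootstrap_mean_test, fdr_bh

logger = logging.getLogger(__name__)

__all__ = [
    "LinearMap",
    "EncodingResults",
    "ZeroShotEncodingModel",
    "fit_ols",
    "predict",
    "score_zero_shot",
    "nearest_train_control",
    "run_encoding",
]

VARIANTS = ("actual", "nearest", "shuffled")


@dataclass
class LinearMap:
    """OLS weights, (dim+1) x electrodes; row 0 is the intercept."""

    weights: np.ndarray
    lag_ms: float | None = None
    fit_fold: int | None = None

    @property
    def dim(self) -> int:
        return self.weights.shape[0] - 1


def fit_ols(
    train_X: np.ndarray,
    train_Y: np.ndarray,
    ridge: float = 0.0,
    allow_singular: bool = False,
) -> LinearMap:
    """Least-squares map embedding -> electrodes with intercept.

    Equals the normal-equations solution; raises on a singular design
    (which also catches |train| <= dim) unless ``allow_singular`` selects
    the minimum-norm solution (used in the decoding direction, where the
    electrode regressors may be collinear).  A small ridge penalty is
    available behind the ``ridge`` flag but is off by default.
    """
    X = np.asarray(train_X, dtype=float)
    Y = np.asarray(train_Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("train_X and train_Y row counts differ")
    design = np.column_stack([np.ones(X.shape[0]), X])
    if X.shape[0] < design.shape[1]:
        raise ValueError(
            f"underdetermined fit: {X.shape[0]} rows for {design.shape[1]} params"
        )
    if ridge > 0.0:
        A = design.T @ design + ridge * np.eye(design.shape[1])
        W = np.linalg.solve(A, design.T @ Y)
        return LinearMap(weights=W)
    W, _, rank, _ = np.linalg.lstsq(design, Y, rcond=None)
    if rank < design.shape[1] and not allow_singular:
        raise ValueError(
            f"singular design matrix (rank {rank} < {design.shape[1]}); "
            "degenerate embeddings?"
        )
    return LinearMap(weights=W)


def predict(lin: LinearMap, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return np.column_stack([np.ones(X.shape[0]), X]) @ lin.weights


def score_zero_shot(
    lin: LinearMap, test_X: np.ndarray, test_Y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-word Pearson r between predicted and observed electrode patterns.

    The correlation runs across electrodes for each held-out word, so at
    least 2 electrodes are required.  Words whose observed pattern has
    zero variance are dropped (r undefined) and logged; returns
    ``(r_values, kept_row_indices)``.
    """
    Y = np.asarray(test_Y, dtype=float)
    if Y.shape[1] < 2:
        raise ValueError("pattern correlation needs at least 2 electrodes")
    P = predict(lin, test_X)
    Pc = P - P.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    pn = np.linalg.norm(Pc, axis=1)
    yn = np.linalg.norm(Yc, axis=1)
    ok = (pn > 0) & (yn > 0)
    n_bad = int((yn == 0).sum())
    if n_bad:
        logger.warning("score_zero_shot: dropped %d zero-variance words", n_bad)
    r = np.einsum("ij,ij->i", Pc[ok], Yc[ok]) / (pn[ok] * yn[ok])
    return r, np.flatnonzero(ok)


def nearest_train_control(
    train_X: np.ndarray, test_X: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Replace each test embedding by its most cosine-similar training row.

    Ties go to the earliest training row (rows are onset-ordered).
    Returns the substituted matrix and the substitution index map.
    """
    A = np.asarray(train_X, dtype=float)
    B = np.asarray(test_X, dtype=float)
    if A.shape[0] == 0:
        raise ValueError("empty training set")
    an = np.linalg.norm(A, axis=1)
    bn = np.linalg.norm(B, axis=1)
    if (an == 0).any() or (bn == 0).any():
        raise ValueError("zero-norm embedding row; cosine similarity undefined")
    sim = (B / bn[:, None]) @ (A / an[:, None]).T
    nearest = sim.argmax(axis=1)  # argmax returns the first (earliest) maximum
    return A[nearest], nearest


def run_encoding(
    brain: dict,
    table,
    folds: FoldSpec,
    variants=("actual",),
    n_shuffles: int = 10,
    seed: int = 0,
    nearest_from_test: bool = False,
    ridge: float = 0.0,
) -> "EncodingResults":
    """Sweep lags x folds x variants and pool per-word correlations.

    Parameters
    ----------
    brain : dict mapping lag (ms) to a words x electrodes array (or an
        object with a ``matrix`` attribute), rows aligned to
        ``folds.events``.
    table : EmbeddingTable aligned to ``folds.events`` rows.
    variants : subset of {"actual", "nearest", "shuffled"}.
    nearest_from_test : draw the nearest neighbor from the other test
        words instead of the training set (less conservative control).
    """
    folds.assert_zero_shot()
    for v in variants:
        if v not in VARIANTS:
            raise ValueError(f"unknown variant {v!r}")
    if table.n_words != folds.n_words:
        raise ValueError("embedding table rows must align with fold events")
    rng = np.random.default_rng(seed)
    records = []
    type_ids = folds.events["type_id"].to_numpy()

    for lag, Y in sorted(brain.items()):
        Y = getattr(Y, "matrix", Y)
        if Y.shape[0] != folds.n_words:
            raise ValueError(f"brain matrix at lag {lag} misaligned with folds")
        for f in range(folds.k):
            tr = folds.train_mask(f)
            te = folds.test_mask(f)
            lin = fit_ols(table.matrix[tr], Y[tr], ridge=ridge)
            lin.lag_ms, lin.fit_fold = float(lag), f
            te_idx = np.flatnonzero(te)
            for variant in variants:
                if variant == "actual":
                    r, kept = score_zero_shot(lin, table.matrix[te], Y[te])
                    _emit(records, lag, variant, f, type_ids[te_idx[kept]], r)
                elif variant == "nearest":
                    if nearest_from_test:
                        Xs = _nearest_within(table.matrix[te])
                    else:
                        Xs, _ = nearest_train_control(
                            table.matrix[tr], table.matrix[te]
                        )
                    r, kept = score_zero_shot(lin, Xs, Y[te])
                    _emit(records, lag, variant, f, type_ids[te_idx[kept]], r)
                else:  # shuffled: average per-word r over random mismatches
                    acc = None
                    for _ in range(n_shuffles):
                        sh = shuffle_assignment(
                            table, te, seed=int(rng.integers(2**31))
                        )
                        r, kept = score_zero_shot(lin, sh.matrix[te], Y[te])
                        acc = r if acc is None else acc + r
                    _emit(
                        records, lag, variant, f, type_ids[te_idx[kept]],
                        acc / n_shuffles,
                    )
    scores = pd.DataFrame.from_records(
        records, columns=["lag_ms", "variant", "fold", "word", "r"]
    )
    return EncodingResults(scores=scores, embedding_kind=table.kind, folds=folds)


def _emit(records, lag, variant, fold, words, r) -> None:
    for w, ri in zip(words, r):
        records.append((float(lag), variant, fold, w, float(ri)))


def _nearest_within(test_X: np.ndarray) -> np.ndarray:
    """Nearest neighbor drawn from the *other* test words (self excluded)."""
    B = np.asarray(test_X, dtype=float)
    bn = np.linalg.norm(B, axis=1)
    if (bn == 0).any():
        raise ValueError("zero-norm embedding row; cosine similarity undefined")
    sim = (B / bn[:, None]) @ (B / bn[:, None]).T
    np.fill_diagonal(sim, -np.inf)
    return B[sim.argmax(axis=1)]


@dataclass
class EncodingResults:
    """Pooled per-word encoding correlations with summary and inference."""

    scores: pd.DataFrame  # columns lag_ms, variant, fold, word, r
    embedding_kind: str = "contextual"
    folds: FoldSpec | None = None

    def per_word_r(self, lag_ms: float, variant: str = "actual") -> pd.Series:
        sel = self.scores[
            (self.scores["lag_ms"] == lag_ms) & (self.scores["variant"] == variant)
        ]
        return sel.set_index("word")["r"]

    def lag_summary(self) -> pd.DataFrame:
        """Per-lag, per-variant mean r with the standard error across words."""
        g = self.scores.groupby(["lag_ms", "variant"])["r"]
        out = g.agg(mean_r="mean", sd="std", n="count").reset_index()
        out["se"] = out["sd"] / np.sqrt(out["n"])
        return out.drop(columns="sd")

    def mean_r(self, lag_ms: float, variant: str = "actual") -> float:
        return float(self.per_word_r(lag_ms, variant).mean())

    def peak_lag(self, variant: str = "actual") -> float:
        s = self.lag_summary()
        s = s[s["variant"] == variant]
        return float(s.loc[s["mean_r"].idxmax(), "lag_ms"])

    def significance(
        self,
        variant: str = "actual",
        n_boot: int = 5000,
        q: float = 0.01,
        seed: int = 0,
    ) -> SignificanceResult:
        """Per-lag bootstrap test of mean r > 0, FDR-corrected over lags."""
        lags = np.sort(self.scores["lag_ms"].unique())
        pvals = np.empty(len(lags))
        for i, lag in enumerate(lags):
            pvals[i] = bootstrap_mean_test(
                self.per_word_r(lag, variant).to_numpy(),
                n_boot=n_boot,
                seed=seed + i,
            )
        flags = fdr_bh(pvals, q=q)
        return SignificanceResult(
            pvals=pvals,
            significant=flags,
            procedure="bootstrap",
            correction=f"fdr q={q}",
            n_resamples=n_boot,
            seed=seed,
        )

    def summary(self) -> str:
        """Human-readable per-lag table in the statsmodels spirit."""
        s = self.lag_summary()
        lines = [
            "Zero-shot encoding results",
            f"  embedding kind: {self.embedding_kind}",
            f"  words: {self.scores['word'].nunique()}   "
            f"lags: {self.scores['lag_ms'].nunique()}   "
            f"variants: {sorted(self.scores['variant'].unique())}",
            "",
            f"{'lag_ms':>9} {'variant':>9} {'mean_r':>9} {'se':>9} {'n':>6}",
        ]
        for _, row in s.iterrows():
            lines.append(
                f"{row['lag_ms']:>9.0f} {row['variant']:>9} "
                f"{row['mean_r']:>9.4f} {row['se']:>9.4f} {int(row['n']):>6d}"
            )
        return "\n".join(lines)

    def to_tsv(self, path, summary_path=None) -> None:
        self.scores.to_csv(path, sep="\t", index=False)
        if summary_path is not None:
            self.lag_summary().to_csv(summary_path, sep="\t", index=False)

    def plot(self, ax=None, variants=None):
        """Per-lag mean r with a standard-error band, one line per variant."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        s = self.lag_summary()
        for v in variants or sorted(s["variant"].unique()):
            sv = s[s["variant"] == v]
            ax.plot(sv["lag_ms"], sv["mean_r"], label=v)
            ax.fill_between(
                sv["lag_ms"],
                sv["mean_r"] - sv["se"],
                sv["mean_r"] + sv["se"],
                alpha=0.3,
            )
        ax.axvline(0, color="k", lw=0.5)
        ax.set_xlabel("lag (ms)")
        ax.set_ylabel("mean correlation (r)")
        ax.legend()
        return ax


class ZeroShotEncodingModel:
    """Encoding model tying embeddings, brain responses and folds together.

    Parameters
    ----------
    table : EmbeddingTable
        Rows aligned to the selected word events (one per type).
    brain : dict lag_ms -> words x electrodes array or BrainEmbedding.
    folds : FoldSpec

    ``fit`` runs the per-lag, per-fold OLS sweep and returns
    :class:`EncodingResults`.
    """

    def __init__(self, table, brain: dict, folds: FoldSpec):
        self.table = table
        self.brain = brain
        self.folds = folds

    @classmethod
    def from_epochs(cls, table, epochs: dict, folds: FoldSpec):
        """Build from :func:`neuroalign.preprocess.epoch_lags` output."""
        return cls(table=table, brain=epochs, folds=folds)

    def fit(
        self,
        variants=("actual",),
        n_shuffles: int = 10,
        seed: int = 0,
        nearest_from_test: bool = False,
        ridge: float = 0.0,
    ) -> EncodingResults:
        return run_encoding(
            self.brain,
            self.table,
            self.folds,
            variants=variants,
            n_shuffles=n_shuffles,
            seed=seed,
            nearest_from_test=nearest_from_test,
            ridge=ridge,
        )
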