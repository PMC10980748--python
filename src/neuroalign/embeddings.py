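"""Embedding tables: contextual, static, symbolic and pseudo-contextual.

Contextual embeddings (per-occurrence vectors from a deep language model)
and static embeddings (one GloVe-style vector per word type) are consumed
as precomputed tables; this module loads, reduces and augments them.  The
75-dimensional symbolic representation is built here from tokens: binary
features for part of speech (11), stopword (1), word shape (16), prefixes
(19) and suffixes (28).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "EmbeddingTable",
    "SymbolicInventory",
    "pca_reduce",
    "build_symbolic",
    "add_symbolic_context",
    "build_pseudo_contextual",
    "load_table",
    "save_table",
]

KINDS = ("contextual", "static", "symbolic", "pseudo")


@dataclass
class EmbeddingTable:
    """Words x dimensions numeric matrix, row-aligned to the event table."""

    matrix: np.ndarray
    kind: str
    provenance: dict = field(default_factory=dict)
    column_names: list | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (words x dimensions)")
        if np.isnan(self.matrix).any():
            raise ValueError("embedding table contains NaN")
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}")

    @property
    def n_words(self) -> int:
        return self.matrix.shape[0]

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]

    def take(self, rows) -> "EmbeddingTable":
        return replace(self, matrix=self.matrix[rows])


# ---------------------------------------------------------------------------
# default symbolic inventory
# ---------------------------------------------------------------------------

# Coarse POS tagset (11 tags, "X" is the catch-all)
_DEFAULT_POS = [
    "NOUN", "VERB", "ADJ", "ADV", "PRON", "DET", "ADP", "NUM", "CONJ",
    "PRT", "X",
]

# Word-shape classes over case/digit/punctuation patterns; "other" is the
# reserved fallback (16 total)
_DEFAULT_SHAPES = [
    "lower", "upper", "title", "mixed", "digit", "digit_lower",
    "digit_upper", "lower_hyphen", "title_hyphen", "upper_hyphen",
    "lower_apostrophe", "title_apostrophe", "punct", "single_lower",
    "single_upper", "other",
]

_DEFAULT_PREFIXES = [
    "un", "re", "in", "im", "dis", "en", "non", "over", "mis", "sub",
    "pre", "inter", "fore", "de", "trans", "super", "semi", "anti", "mid",
]

_DEFAULT_SUFFIXES = [
    "s", "es", "ed", "ing", "ly", "er", "or", "ion", "tion", "ation",
    "ition", "able", "ible", "al", "ial", "ness", "ity", "ty", "ment",
    "ic", "ous", "eous", "ious", "en", "ive", "ative", "ful", "less",
]


def _default_stopwords() -> frozenset:
    from sklearn.feature_extraction.text import ENGLISH_STOP_WORDS

    return frozenset(ENGLISH_STOP_WORDS)


@dataclass
class SymbolicInventory:
    """Feature inventory for the 75-dimensional symbolic representation.

    Group sizes are enforced exactly: 11 POS tags, one stopword lexicon,
    16 shape classes, 19 prefixes, 28 suffixes (75 features in total).
    Any group can be overridden, including from a TOML file.
    """

    pos_tags: list = field(default_factory=lambda: list(_DEFAULT_POS))
    stopword_lexicon: frozenset = field(default_factory=_default_stopwords)
    shape_classes: list = field(default_factory=lambda: list(_DEFAULT_SHAPES))
    prefix_list: list = field(default_factory=lambda: list(_DEFAULT_PREFIXES))
    suffix_list: list = field(default_factory=lambda: list(_DEFAULT_SUFFIXES))

    def __post_init__(self) -> None:
        sizes = (
            len(self.pos_tags),
            len(self.shape_classes),
            len(self.prefix_list),
            len(self.suffix_list),
        )
        if sizes != (11, 16, 19, 28):
            raise ValueError(
                "inventory group sizes must be POS=11, shapes=16, "
                f"prefixes=19, suffixes=28; got {sizes}"
            )
        if "other" not in self.shape_classes:
            raise ValueError("shape_classes must include the reserved 'other'")

    @property
    def dim(self) -> int:
        return 11 + 1 + 16 + 19 + 28  # = 75

    @classmethod
    def from_toml(cls, path) -> "SymbolicInventory":
        import tomllib

        with open(path, "rb") as f:
            cfg = tomllib.load(f)
        kwargs = {}
        for key in ("pos_tags", "shape_classes", "prefix_list", "suffix_list"):
            if key in cfg:
                kwargs[key] = list(cfg[key])
        if "stopword_lexicon" in cfg:
            kwargs["stopword_lexicon"] = frozenset(cfg["stopword_lexicon"])
        return cls(**kwargs)


def _word_shape(token: str) -> str:
    if re.fullmatch(r"[a-z]", token):
        return "single_lower"
    if re.fullmatch(r"[A-Z]", token):
        return "single_upper"
    if re.fullmatch(r"[a-z]+", token):
        return "lower"
    if re.fullmatch(r"[A-Z]+", token):
        return "upper"
    if re.fullmatch(r"[A-Z][a-z]+", token):
        return "title"
    if re.fullmatch(r"[0-9]+", token):
        return "digit"
    if re.fullmatch(r"[a-z0-9]+", token):
        return "digit_lower"
    if re.fullmatch(r"[A-Z0-9]+", token):
        return "digit_upper"
    if re.fullmatch(r"[a-z]+(-[a-z]+)+", token):
        return "lower_hyphen"
    if re.fullmatch(r"[A-Z][a-z]*(-[A-Za-z][a-z]*)+", token):
        return "title_hyphen"
    if re.fullmatch(r"[A-Z]+(-[A-Z]+)+", token):
        return "upper_hyphen"
    if re.fullmatch(r"[a-z]+'[a-z]+", token):
        return "lower_apostrophe"
    if re.fullmatch(r"[A-Z][a-z]*'[a-z]+", token):
        return "title_apostrophe"
    if re.fullmatch(r"[^\w\s]+", token):
        return "punct"
    if re.fullmatch(r"[A-Za-z]+", token):
        return "mixed"
    return "other"


_SUFFIX_TAG_GUESS = [
    ("ly", "ADV"), ("ing", "VERB"), ("ed", "VERB"), ("ous", "ADJ"),
    ("ive", "ADJ"), ("able", "ADJ"), ("ible", "ADJ"), ("ful", "ADJ"),
    ("less", "ADJ"), ("tion", "NOUN"), ("ment", "NOUN"), ("ness", "NOUN"),
    ("ity", "NOUN"),
]

_CLOSED_CLASS = {
    "the": "DET", "a": "DET", "an": "DET", "this": "DET", "that": "DET",
    "i": "PRON", "you": "PRON", "he": "PRON", "she": "PRON", "it": "PRON",
    "we": "PRON", "they": "PRON", "me": "PRON", "him": "PRON", "her": "PRON",
    "of": "ADP", "in": "ADP", "on": "ADP", "at": "ADP", "to": "PRT",
    "by": "ADP", "with": "ADP", "from": "ADP", "for": "ADP",
    "and": "CONJ", "or": "CONJ", "but": "CONJ", "if": "CONJ",
    "not": "ADV", "very": "ADV",
    "one": "NUM", "two": "NUM", "three": "NUM",
}


def _guess_pos(token: str) -> str:
    """Crude lexicon/suffix POS heuristic used when no tag column is given."""
    low = token.lower()
    if low in _CLOSED_CLASS:
        return _CLOSED_CLASS[low]
    if low.isdigit():
        return "NUM"
    for suf, tag in _SUFFIX_TAG_GUESS:
        if low.endswith(suf) and len(low) > len(suf):
            return tag
    if low.isalpha():
        return "NOUN"
    return "X"


def build_symbolic(
    tokens,
    inv: SymbolicInventory | None = None,
    pos: list | None = None,
) -> EmbeddingTable:
    """Binary 75-dimensional symbolic vectors, one per token.

    POS is one-hot (from the supplied ``pos`` sequence, falling back to a
    built-in heuristic tagger); stopword is a single bit; shape is one-hot
    over the 16 classes (tokens matching none go to the reserved "other"
    class); prefixes and suffixes are multi-hot substring matches.
    """
    if inv is None:
        inv = SymbolicInventory()
    tokens = list(tokens)
    n = len(tokens)
    if pos is not None and len(pos) != n:
        raise ValueError("pos column length must match tokens")

    mat = np.zeros((n, inv.dim))
    names = (
        [f"pos={t}" for t in inv.pos_tags]
        + ["stopword"]
        + [f"shape={s}" for s in inv.shape_classes]
        + [f"prefix={p}" for p in inv.prefix_list]
        + [f"suffix={s}" for s in inv.suffix_list]
    )
    pos_idx = {t: i for i, t in enumerate(inv.pos_tags)}
    shape_idx = {s: i for i, s in enumerate(inv.shape_classes)}
    off_stop = 11
    off_shape = 12
    off_pref = 12 + 16
    off_suf = 12 + 16 + 19

    for i, tok in enumerate(tokens):
        tag = pos[i] if pos is not None else _guess_pos(tok)
        mat[i, pos_idx.get(tag, pos_idx.get("X", len(inv.pos_tags) - 1))] = 1.0
        low = tok.lower()
        if low in inv.stopword_lexicon:
            mat[i, off_stop] = 1.0
        shp = _word_shape(tok)
        if shp not in shape_idx:
            logger.info("token %r: shape %r not in inventory, using 'other'", tok, shp)
            shp = "other"
        mat[i, off_shape + shape_idx[shp]] = 1.0
        for j, p in enumerate(inv.prefix_list):
            if low.startswith(p) and len(low) > len(p):
                mat[i, off_pref + j] = 1.0
        for j, s in enumerate(inv.suffix_list):
            if low.endswith(s) and len(low) > len(s):
                mat[i, off_suf + j] = 1.0

    return EmbeddingTable(
        matrix=mat,
        kind="symbolic",
        provenance={"source": "build_symbolic"},
        column_names=names,
    )


def add_symbolic_context(table: EmbeddingTable, n_prev: int = 3) -> EmbeddingTable:
    """Concatenate each symbolic row with its ``n_prev`` predecessors.

    Zero padding at the stream start; output dimension is
    ``dim * (1 + n_prev)`` (300 for the 75-dim default with 3 context
    words).
    """
    if table.kind != "symbolic":
        raise ValueError("add_symbolic_context requires a symbolic table")
    blocks = [table.matrix]
    for j in range(1, n_prev + 1):
        shifted = np.zeros_like(table.matrix)
        if j < table.n_words:
            shifted[j:] = table.matrix[:-j]
        blocks.append(shifted)
    return EmbeddingTable(
        matrix=np.hstack(blocks),
        kind="symbolic",
        provenance={**table.provenance, "context_words": n_prev},
    )


def build_pseudo_contextual(
    static_table: EmbeddingTable, history: int = 10
) -> EmbeddingTable:
    """Concatenate the static embeddings of the previous ``history`` words.

    Row ``t`` becomes ``concat(rows t-history ... t-1, row t)`` with zero
    padding at the start; a pseudo-contextual control that carries context
    information without a language model.
    """
    if static_table.kind != "static":
        raise ValueError("build_pseudo_contextual requires a static table")
    blocks = []
    for j in range(history, 0, -1):
        shifted = np.zeros_like(static_table.matrix)
        if j < static_table.n_words:
            shifted[j:] = static_table.matrix[:-j]
        blocks.append(shifted)
    blocks.append(static_table.matrix)
    return EmbeddingTable(
        matrix=np.hstack(blocks),
        kind="pseudo",
        provenance={**static_table.provenance, "history": history},
    )


def pca_reduce(
    table: EmbeddingTable,
    n_components: int = 50,
    fit_rows=None,
) -> EmbeddingTable:
    """Project the table onto its leading principal axes.

    The axes are fit on ``fit_rows`` only (all rows when None) and every
    row is projected, so a leakage-safe reduction fits on the training
    folds of the current split.  Components are ordered by decreasing
    explained variance; the explained variances are stored in provenance.
    """
    from sklearn.decomposition import PCA

    X = table.matrix
    fit = X if fit_rows is None else X[np.asarray(fit_rows)]
    if n_components > min(fit.shape[0], X.shape[1]):
        raise ValueError(
            f"n_components={n_components} exceeds min(fit rows, dim) "
            f"= {min(fit.shape[0], X.shape[1])}"
        )
    rank = np.linalg.matrix_rank(fit - fit.mean(axis=0))
    if rank < n_components:
        raise ValueError(
            f"fit set is rank deficient: rank {rank} < {n_components} components"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(fit)
    out = pca.transform(X)
    prov = {
        **table.provenance,
        "pca_components": n_components,
        "explained_variance": pca.explained_variance_,
        "fit_scope": "global" if fit_rows is None else "subset",
    }
    return EmbeddingTable(matrix=out, kind=table.kind, provenance=prov)


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------


def save_table(table: EmbeddingTable, path) -> None:
    """Write a table as TSV (header = dimension names) or HDF5 (.h5/.hdf5)."""
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(path, "w") as f:
            d = f.create_dataset("matrix", data=table.matrix)
            d.attrs["kind"] = table.kind
    else:
        names = table.column_names or [f"d{j}" for j in range(table.dim)]
        pd.DataFrame(table.matrix, columns=names).to_csv(path, sep="\t", index=False)


def load_table(path, kind: str, expected_rows: int | None = None) -> EmbeddingTable:
    """Load a TSV or HDF5 embedding table; row count may be validated."""
    path = str(path)
    names = None
    if path.endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(path, "r") as f:
            matrix = f["matrix"][()]
            kind = f["matrix"].attrs.get("kind", kind)
    else:
        df = pd.read_csv(path, sep="\t")
        matrix = df.to_numpy(dtype=float)
        names = list(df.columns)
    if expected_rows is not None and matrix.shape[0] != expected_rows:
        raise ValueError(
            f"row count mismatch: table has {matrix.shape[0]} rows, "
            f"event table has {expected_rows}"
        )
    return EmbeddingTable(
        matrix=matrix, kind=kind, provenance={"source": path}, column_names=names
    )
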