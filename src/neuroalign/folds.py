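"""Unique-word selection and contiguous cross-validation folds.

The zero-shot scheme selects one occurrence of every word type at random,
sorts the selected events by stimulus time and partitions them into k
contiguous folds of near-equal size.  Because every type contributes
exactly one event, no type can appear in both a training and a test fold
— the central control of the analysis, re-asserted on every run via
:meth:`FoldSpec.assert_zero_shot`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FoldSpec",
    "select_unique_instances",
    "make_folds",
    "shuffle_assignment",
]


@dataclass
class FoldSpec:
    """Onset-sorted selected events with a contiguous fold assignment.

    ``events`` has one row per selected word event (one per type) and a
    ``fold`` column in ``0..k-1``; folds are contiguous in stimulus time
    and differ in size by at most one (remainder events go to the earliest
    folds).
    """

    events: pd.DataFrame
    k: int
    seed: int | None = None

    def __post_init__(self) -> None:
        self.assert_zero_shot()

    @property
    def n_words(self) -> int:
        return len(self.events)

    @property
    def fold_of(self) -> dict:
        return dict(zip(self.events["type_id"], self.events["fold"]))

    def test_mask(self, fold: int) -> np.ndarray:
        return (self.events["fold"] == fold).to_numpy()

    def train_mask(self, fold: int) -> np.ndarray:
        return ~self.test_mask(fold)

    def fold_sizes(self) -> np.ndarray:
        return self.events["fold"].value_counts().sort_index().to_numpy()

    def assert_zero_shot(self) -> None:
        """Every word type lives in exactly one fold; folds are contiguous."""
        ev = self.events
        if ev["type_id"].duplicated().any():
            raise AssertionError(
                "zero-shot violation: a word type appears more than once"
            )
        folds = ev.sort_values("onset_s")["fold"].to_numpy()
        changes = np.flatnonzero(np.diff(folds) != 0)
        if len(changes) >= self.k:
            raise AssertionError("folds are not contiguous in stimulus time")

    def to_tsv(self, path) -> None:
        self.events[["token", "onset_s", "type_id", "fold"]].to_csv(
            path, sep="\t", index=False
        )


def select_unique_instances(stream, seed: int = 0) -> pd.DataFrame:
    """Choose one occurrence per word type, uniformly at random.

    Returns the selected events sorted by onset, keeping the original
    event-table index in ``event_idx``.
    """
    rng = np.random.default_rng(seed)
    events = stream.events if hasattr(stream, "events") else stream
    if len(events) == 0:
        raise ValueError("empty stream")
    picks = []
    for _, grp in events.groupby("type_id", sort=True):
        picks.append(grp.index[rng.integers(len(grp))])
    sel = events.loc[picks].copy()
    sel["event_idx"] = sel.index
    sel = sel.sort_values("onset_s").reset_index(drop=True)
    return sel


def make_folds(selected: pd.DataFrame, k: int = 10, seed: int | None = None) -> FoldSpec:
    """Partition onset-sorted events into k contiguous near-equal folds."""
    if k <= 0:
        raise ValueError("k must be positive")
    n = len(selected)
    if n < k:
        raise ValueError(f"need at least k={k} selected events, got {n}")
    sel = selected.sort_values("onset_s").reset_index(drop=True)
    base, rem = divmod(n, k)
    sizes = [base + 1 if f < rem else base for f in range(k)]
    fold = np.repeat(np.arange(k), sizes)
    sel = sel.copy()
    sel["fold"] = fold
    return FoldSpec(events=sel, k=k, seed=seed)


def shuffle_assignment(table, fold_mask: np.ndarray, seed: int = 0,
                       derange: bool = True):
    """Permute the embedding rows of the test fold (mismatch control).

    By default the permutation is a derangement (no word keeps its own
    embedding: every test word gets a *mismatching* embedding); pass
    ``derange=False`` for a plain uniform permutation.  Training rows are
    untouched.  Returns a new table; the multiset of rows is preserved.
    """
    from dataclasses import replace

    fold_mask = np.asarray(fold_mask, dtype=bool)
    rng = np.random.default_rng(seed)
    idx = np.flatnonzero(fold_mask)
    perm = rng.permutation(len(idx))
    if derange and len(idx) > 1:
        while (perm == np.arange(len(idx))).any():
            perm = rng.permutation(len(idx))
    matrix = table.matrix.copy()
    matrix[idx] = matrix[idx[perm]]
    return replace(table, matrix=matrix)
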