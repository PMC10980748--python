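import numpy as np
import pandas as pd
import pytest

from neuroalign import synthetic
from neuroalign.folds import make_folds, select_unique_instances


def row_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r between matching rows (textbook formula)."""
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    return (a * b).sum(axis=1) / (
        np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
    )


def standardize_columns(m: np.ndarray) -> np.ndarray:
    sd = m.std(axis=0)
    sd[sd == 0] = 1.0
    return (m - m.mean(axis=0)) / sd


@pytest.fixture(scope="session")
def small_stream():
    return synthetic.generate_stream(
        n_types=80, n_tokens=200, duration_s=200.0, zipf_s=1.1, seed=11
    )


@pytest.fixture(scope="session")
def small_table(small_stream):
    return synthetic.generate_contextual_table(
        small_stream, embed_dim=20, cone_angle_deg=20.0, seed=12
    )


@pytest.fixture(scope="session")
def ground_truth():
    rng = np.random.default_rng(13)
    W = rng.standard_normal((30, 20)) / np.sqrt(20)
    return synthetic.GroundTruth(map_matrix=W)


@pytest.fixture(scope="session")
def small_folds(small_stream):
    sel = select_unique_instances(small_stream, seed=14)
    return make_folds(sel, k=10, seed=14)


@pytest.fixture(scope="session")
def selected_table(small_table, small_folds):
    return small_table.take(small_folds.events["event_idx"].to_numpy())


@pytest.fixture(scope="session")
def selected_events(small_folds):
    class _Stream:
        events = small_folds.events

    return _Stream()
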