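"""Zero-shot encoding: OLS fitting, scoring, controls and invariants."""

import numpy as np
import pytest

from neuroalign import synthetic
from neuroalign.encoding import (
    ZeroShotEncodingModel,
    fit_ols,
    nearest_train_control,
    predict,
    run_encoding,
    score_zero_shot,
)

class TestFitOLS:
    def test_noiseless_weights_recovered(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((40, 5))
        W = rng.standard_normal((5, 7))
        b = rng.standard_normal(7)
        Y = X @ W + b
        lin = fit_ols(X, Y)
        assert np.allclose(lin.weights[0], b, atol=1e-8)
        assert np.allclose(lin.weights[1:], W, atol=1e-8)

    def test_constant_column_flagged_singular(self):
        X = np.ones((30, 1))  # collinear with the intercept
        Y = np.random.default_rng(1).standard_normal((30, 3))
        with pytest.raises(ValueError, match="singular"):
            fit_ols(X, Y)

    def test_underdetermined_rejected(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError, match="underdetermined"):
            fit_ols(rng.standard_normal((4, 6)), rng.standard_normal((4, 2)))

    def test_matches_pseudoinverse_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            X = rng.standard_normal((20, 5))
            Y = rng.standard_normal((20, 4))
            D = np.column_stack([np.ones(20), X])
            oracle = np.linalg.pinv(D) @ Y
            lin = fit_ols(X, Y)
            assert np.allclose(lin.weights, oracle, atol=1e-10)


class TestScoreZeroShot:
    def make_perfect(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((30, 4))
        W = rng.standard_normal((4, 8))
        Y = X @ W
        return fit_ols(X, Y), X, Y

    def test_perfect_predictions_r_one(self):
        lin, X, Y = self.make_perfect()
        r, kept = score_zero_shot(lin, X, Y)
        assert np.allclose(r, 1.0)
        assert len(kept) == 30

    def test_anti_predictions_r_minus_one(self):
        lin, X, Y = self.make_perfect()
        r, _ = score_zero_shot(lin, X, -Y)
        assert np.allclose(r, -1.0)

    def test_matches_textbook_pearson(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((25, 4))
        Y = rng.standard_normal((25, 8))
        lin = fit_ols(X, Y)
        r, _ = score_zero_shot(lin, X, Y)
        P = predict(lin, X)
        oracle = np.array([np.corrcoef(P[i], Y[i])[0, 1] for i in range(25)])
        assert np.allclose(r, oracle, atol=1e-12)

    def test_zero_variance_word_dropped(self):
        lin, X, Y = self.make_perfect()
        Y = Y.copy()
        Y[3] = 5.0  # flat observed pattern
        r, kept = score_zero_shot(lin, X, Y)
        assert 3 not in kept
        assert len(r) == 29


class TestNearestTrainControl:
    def test_identical_row_substituted(self):
        rng = np.random.default_rng(6)
        train = rng.standard_normal((10, 4))
        test = train[[2, 7]] * 3.0  # same direction, different norm
        sub, idx = nearest_train_control(train, test)
        assert idx.tolist() == [2, 7]
        assert np.array_equal(sub, train[[2, 7]])

    def test_singleton_train_always_chosen(self):
        train = np.array([[1.0, 0.0]])
        test = np.array([[0.0, 1.0], [0.5, 0.5]])
        sub, idx = nearest_train_control(train, test)
        assert (idx == 0).all()

    def test_matches_exhaustive_cosine_argmax(self):
        rng = np.random.default_rng(7)
        train = rng.standard_normal((50, 20))
        test = rng.standard_normal((12, 20))
        _, idx = nearest_train_control(train, test)
        for i in range(12):
            sims = [
                test[i] @ train[j] / (np.linalg.norm(test[i]) * np.linalg.norm(train[j]))
                for j in range(50)
            ]
            assert idx[i] == int(np.argmax(sims))

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError, match="zero-norm"):
            nearest_train_control(np.zeros((3, 4)), np.ones((2, 4)))


@pytest.fixture(scope="module")
def oracle_setup(selected_events, selected_table, ground_truth):
    return synthetic.oracle_brain_embeddings(
        selected_events, selected_table, ground_truth,
        [100.0, 200.0, 300.0], noise_sd=0.02, seed=20,
    )


class TestRunEncoding:
    def test_actual_variant_recovers_geometry(self, oracle_setup, selected_table,
                                              small_folds):
        res = run_encoding(oracle_setup, selected_table, small_folds,
                           variants=("actual",))
        assert res.mean_r(200.0) > 0.95

    def test_shuffled_variant_at_chance(self, oracle_setup, selected_table,
                                        small_folds):
        res = run_encoding(oracle_setup, selected_table, small_folds,
                           variants=("shuffled",), n_shuffles=10, seed=0)
        r = res.per_word_r(200.0, "shuffled")
        ci = 1.96 * r.std() / np.sqrt(len(r))
        assert abs(r.mean()) < ci + 0.02

    def test_actual_beats_nearest_for_contextual_geometry(
        self, oracle_setup, selected_table, small_folds
    ):
        res = run_encoding(oracle_setup, selected_table, small_folds,
                           variants=("actual", "nearest"))
        assert res.mean_r(200.0, "actual") > res.mean_r(200.0, "nearest")

    def test_contextual_beats_static_collapse(self, selected_events, small_folds,
                                              selected_table, ground_truth):
        """Collapsing each type to its mean direction loses within-type detail."""
        from neuroalign.embeddings import EmbeddingTable

        brain = synthetic.oracle_brain_embeddings(
            selected_events, selected_table, ground_truth, [200.0],
            noise_sd=0.05, seed=21,
        )
        res_ctx = run_encoding(brain, selected_table, small_folds)
        # static collapse: one vector per type = the normalized mean over all
        # of that type's occurrence embeddings (the cone center estimate)
        full = self._full_table(small_folds)
        res_static = run_encoding(brain, full, small_folds)
        assert res_ctx.mean_r(200.0) > res_static.mean_r(200.0)

    @staticmethod
    def _full_table(small_folds):
        # recreated here so the collapse uses every occurrence, not just the
        # selected instances
        from neuroalign.embeddings import EmbeddingTable
        from neuroalign import synthetic as syn

        stream = syn.generate_stream(
            n_types=80, n_tokens=200, duration_s=200.0, zipf_s=1.1, seed=11
        )
        table = syn.generate_contextual_table(
            stream, embed_dim=20, cone_angle_deg=20.0, seed=12
        )
        tids = stream.events["type_id"].to_numpy()
        means = np.zeros((80, table.dim))
        for t in range(80):
            m = table.matrix[tids == t].mean(axis=0)
            means[t] = m / np.linalg.norm(m)
        sel_tids = small_folds.events["type_id"].to_numpy()
        return EmbeddingTable(matrix=means[sel_tids], kind="static")

    def test_no_cross_test_coupling(self, oracle_setup, selected_table, small_folds):
        """Dropping one test word leaves the other words' scores unchanged."""
        res = run_encoding(
            {200.0: oracle_setup[200.0]}, selected_table, small_folds
        )
        # recompute fold 0 scores manually without one test word
        tr = small_folds.train_mask(0)
        te_idx = np.flatnonzero(small_folds.test_mask(0))
        lin = fit_ols(selected_table.matrix[tr], oracle_setup[200.0][tr])
        keep = te_idx[1:]  # drop the first test word
        r, _ = score_zero_shot(
            lin, selected_table.matrix[keep], oracle_setup[200.0][keep]
        )
        words = small_folds.events["type_id"].to_numpy()[keep]
        full = res.per_word_r(200.0)
        for w, ri in zip(words, r):
            assert full.loc[w] == pytest.approx(ri, abs=1e-12)

    def test_electrode_permutation_destroys_alignment(
        self, oracle_setup, selected_table, small_folds
    ):
        """Permuting electrodes in test_Y breaks the shared geometry."""
        rng = np.random.default_rng(23)
        Y = oracle_setup[200.0].copy()
        for f in range(small_folds.k):
            te = small_folds.test_mask(f)
            Y[te] = Y[te][:, rng.permutation(Y.shape[1])]
        res = run_encoding({200.0: Y}, selected_table, small_folds)
        r = res.per_word_r(200.0)
        ci = 1.96 * r.std() / np.sqrt(len(r))
        assert abs(r.mean()) < ci + 0.05

    def test_misaligned_table_rejected(self, oracle_setup, small_folds,
                                       small_table):
        with pytest.raises(ValueError, match="align"):
            run_encoding(oracle_setup, small_table, small_folds)


class TestModelObject:
    def test_model_fit_equals_function(self, selected_events, selected_table,
                                       ground_truth, small_folds):
        brain = synthetic.oracle_brain_embeddings(
            selected_events, selected_table, ground_truth, [200.0],
            noise_sd=0.1, seed=30,
        )
        res_fn = run_encoding(brain, selected_table, small_folds, seed=5)
        res_obj = ZeroShotEncodingModel(selected_table, brain, small_folds).fit(seed=5)
        assert res_fn.scores.equals(res_obj.scores)

    def test_summary_mentions_lags_and_variants(self, selected_events,
                                                selected_table, ground_truth,
                                                small_folds):
        brain = synthetic.oracle_brain_embeddings(
            selected_events, selected_table, ground_truth, [200.0], seed=31
        )
        res = ZeroShotEncodingModel(selected_table, brain, small_folds).fit()
        text = res.summary()
        assert "actual" in text and "200" in text

    def test_significance_flags_positive_signal(self, selected_events,
                                                selected_table, ground_truth,
                                                small_folds):
        brain = synthetic.oracle_brain_embeddings(
            selected_events, selected_table, ground_truth, [200.0, 3900.0],
            noise_sd=0.05, seed=32,
        )
        res = ZeroShotEncodingModel(selected_table, brain, small_folds).fit()
        sig = res.significance(n_boot=500, q=0.01, seed=0)
        assert sig.significant[0]  # peak lag clearly aligned
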