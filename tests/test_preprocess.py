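"""Despiking, referencing, HFBB power, smoothing and lagged epoching."""

import numpy as np
import pandas as pd
import pytest

from neuroalign import preprocess as pp


def make_raw(signal, fs=512.0):
    signal = np.atleast_2d(np.asarray(signal, dtype=float))
    meta = pd.DataFrame(
        {"participant": ["p1"] * signal.shape[0], "region": ["IFG"] * signal.shape[0]}
    )
    return pp.RawRecording(signal=signal, fs_hz=fs, electrode_meta=meta)


class TestDespike:
    def test_single_impulse_on_constant_removed(self):
        x = np.full(200, 3.0)
        x[77] = 500.0
        out = pp.despike(make_raw(x))
        assert out.signal[0, 77] == pytest.approx(3.0, abs=1e-6)
        mask = np.ones(200, dtype=bool)
        mask[77] = False
        assert np.array_equal(out.signal[0, mask], x[mask])

    def test_clean_signal_identity(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(500)
        out = pp.despike(make_raw(x))
        assert np.array_equal(out.signal[0], x)

    def test_injected_spikes_flagged_low_false_positives(self):
        from neuroalign import synthetic

        s = synthetic.generate_stream(5, 8, 15.0, seed=2)
        t = synthetic.generate_contextual_table(s, 4, 10.0, seed=2)
        gt = synthetic.GroundTruth(map_matrix=np.zeros((4, 4)), spike_rate=40.0,
                                   noise_sd=0.1)
        rec = synthetic.generate_recording(s, t, gt, seed=3)
        out = pp.despike(rec)
        flags = out.meta["despike_flags"]
        for e, i in rec.meta["spike_samples"]:
            assert flags[e, i]
        n_injected = len(rec.meta["spike_samples"])
        fp_rate = (flags.sum() - n_injected) / flags.size
        assert fp_rate < 0.01

    def test_edge_spike_imputed_finite(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(300)
        x[0] = 1e5
        x[-1] = -1e5
        out = pp.despike(make_raw(x))
        assert np.isfinite(out.signal).all()
        assert abs(out.signal[0, 0]) < 100 and abs(out.signal[0, -1]) < 100


class TestCAR:
    def test_two_identical_electrodes_cancel(self):
        x = np.vstack([np.arange(50.0), np.arange(50.0)])
        out = pp.common_average_reference(make_raw(x))
        assert np.allclose(out.signal, 0.0)

    def test_column_means_zero(self):
        rng = np.random.default_rng(2)
        out = pp.common_average_reference(make_raw(rng.standard_normal((5, 300))))
        assert np.allclose(out.signal.mean(axis=0), 0.0)

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((4, 100))
        out = pp.common_average_reference(make_raw(x))
        naive = np.array([x[:, j] - x[:, j].mean() for j in range(100)]).T
        assert np.allclose(out.signal, naive)

    def test_single_electrode_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            pp.common_average_reference(make_raw(np.zeros((1, 100))))


class TestHFBB:
    def test_line_frequency_excluded(self):
        """A pure 120 Hz tone leaves near-flat output; a 140 Hz AM tone does not."""
        fs = 512.0
        t = np.arange(int(10 * fs)) / fs
        env = 1.0 + 0.5 * np.sin(2 * np.pi * 0.7 * t)
        line = np.sin(2 * np.pi * 120.0 * t)
        am = env * np.sin(2 * np.pi * 140.0 * t)
        out = pp.hfbb_power(make_raw(np.vstack([line, am]), fs=fs))
        mid = slice(int(fs), int(9 * fs))  # avoid edge effects
        assert out.power[0, mid].std() < 0.2 * out.power[1, mid].std()

    def test_am_envelope_tracked(self):
        """Output follows the squared (log) envelope of an AM carrier."""
        fs = 512.0
        t = np.arange(int(20 * fs)) / fs
        env = 1.0 + 0.4 * np.sin(2 * np.pi * 0.5 * t)
        sig = np.vstack([env * np.sin(2 * np.pi * 140.0 * t),
                         np.sin(2 * np.pi * 95.0 * t)])
        out = pp.smooth_zero_phase(pp.hfbb_power(make_raw(sig, fs=fs)))
        mid = slice(int(2 * fs), int(18 * fs))
        target = np.log(env[mid] ** 2)
        r = np.corrcoef(out.power[0, mid], target)[0, 1]
        assert r > 0.9

    def test_z_scored_per_electrode(self):
        rng = np.random.default_rng(4)
        out = pp.hfbb_power(make_raw(rng.standard_normal((3, 4096))))
        assert np.allclose(out.power.mean(axis=1), 0.0, atol=1e-6)
        assert np.allclose(out.power.std(axis=1), 1.0, atol=1e-6)

    def test_center_exclusion_grid(self):
        centers = pp._wavelet_centers((70, 200), 5.0, (60, 120, 180), 5.0)
        assert len(centers) == 21
        for f0 in (115, 120, 125, 175, 180, 185):
            assert f0 not in centers

    def test_nyquist_guard(self):
        with pytest.raises(ValueError, match="sampling rate"):
            pp.hfbb_power(make_raw(np.zeros((2, 100)), fs=300.0))


class TestSmoothing:
    def make_sig(self, power, fs=512.0):
        return pp.HFBBSignal(power=np.atleast_2d(power).astype(float), fs_hz=fs)

    def test_impulse_gives_symmetric_kernel(self):
        x = np.zeros(201)
        x[100] = 1.0
        out = pp.smooth_zero_phase(self.make_sig(x)).power[0]
        assert np.argmax(out) == 100
        assert np.allclose(out[100 - 30 : 100], out[101 : 101 + 30][::-1], atol=1e-12)

    def test_constant_preserved(self):
        out = pp.smooth_zero_phase(self.make_sig(np.full(300, 2.5))).power[0]
        assert np.allclose(out, 2.5)

    def test_matches_two_pass_convolution_oracle(self):
        # direct double-loop convolution with reflect (edge-repeat) padding;
        # odd symmetric kernel so the centering is unambiguous
        from scipy.signal.windows import hamming

        rng = np.random.default_rng(5)
        x = rng.standard_normal(100)
        fs = 220.0
        n = int(round(50 * fs / 1000))
        assert n % 2 == 1
        w = hamming(n)
        w /= w.sum()

        def reflect(i, N):
            while i < 0 or i >= N:
                i = -i - 1 if i < 0 else 2 * N - 1 - i
            return i

        def one_pass(sig):
            out = np.empty_like(sig)
            for i in range(len(sig)):
                out[i] = sum(
                    w[j] * sig[reflect(i - n // 2 + j, len(sig))] for j in range(n)
                )
            return out

        oracle = one_pass(one_pass(x[::-1])[::-1])  # backward then forward
        out = pp.smooth_zero_phase(self.make_sig(x, fs=fs)).power[0]
        assert np.allclose(out, oracle, atol=1e-10)


class TestEpoching:
    def test_window_is_102_samples_at_512hz(self):
        grid = pp.LagGrid()
        assert grid.window_samples(512.0) == 102

    def test_default_grid_has_321_lags(self):
        assert len(pp.LagGrid()) == 321

    def test_constant_signal_gives_constant_embedding(self):
        sig = pp.HFBBSignal(power=np.full((3, 5120), 7.0), fs_hz=512.0)
        events = pd.DataFrame({"onset_s": [3.0, 5.0, 7.0]})
        out = pp.epoch_lags(sig, events, pp.LagGrid(-200, 200, 100))
        for emb in out.values():
            assert np.allclose(emb.matrix, 7.0)

    def test_matches_slice_and_mean_oracle(self):
        rng = np.random.default_rng(6)
        power = rng.standard_normal((2, 4096))
        fs = 512.0
        sig = pp.HFBBSignal(power=power, fs_hz=fs)
        events = pd.DataFrame({"onset_s": [2.0, 4.0]})
        grid = pp.LagGrid(-100, 100, 50, window_ms=200)
        out = pp.epoch_lags(sig, events, grid)
        n_win = 102
        for lag, emb in out.items():
            for i, onset in enumerate(events["onset_s"]):
                c = int(round((onset + lag / 1000) * fs))
                s = c - n_win // 2
                expected = power[:, s : s + n_win].mean(axis=1)
                assert np.allclose(emb.matrix[i], expected)

    def test_out_of_range_events_dropped_with_warning(self):
        sig = pp.HFBBSignal(power=np.zeros((2, 1024)), fs_hz=512.0)
        events = pd.DataFrame({"onset_s": [0.05, 1.0]})
        with pytest.warns(UserWarning, match="dropped"):
            out = pp.epoch_lags(sig, events, pp.LagGrid(-200, 200, 200))
        emb = next(iter(out.values()))
        assert emb.n_words == 1
        assert emb.event_index.tolist() == [1]

    def test_no_events_retained_is_error(self):
        sig = pp.HFBBSignal(power=np.zeros((2, 256)), fs_hz=512.0)
        events = pd.DataFrame({"onset_s": [0.01]})
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="no events retained"):
                pp.epoch_lags(sig, events, pp.LagGrid(-200, 200, 200))


def test_epoch_hdf5_round_trip(tmp_path):
    rng = np.random.default_rng(8)
    sig = pp.HFBBSignal(power=rng.standard_normal((3, 4096)), fs_hz=512.0)
    events = pd.DataFrame({"onset_s": [2.0, 3.5, 5.0]})
    epochs = pp.epoch_lags(sig, events, pp.LagGrid(-100, 100, 100))
    path = tmp_path / "epochs.h5"
    pp.save_epochs(epochs, path)
    back = pp.load_epochs(path)
    assert sorted(back) == sorted(epochs)
    for lag in epochs:
        assert np.allclose(back[lag].matrix, epochs[lag].matrix)
        assert np.array_equal(back[lag].event_index, epochs[lag].event_index)


def test_provenance_records_pipeline_order():
    rng = np.random.default_rng(7)
    raw = make_raw(rng.standard_normal((3, 4096)))
    sig = pp.preprocess_raw(raw)
    steps = sig.provenance
    assert [s.split("(")[0] for s in steps] == [
        "despike", "common_average_reference", "hfbb_power", "smooth_zero_phase",
    ]
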