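"""Raw-voltage to high-frequency-broadband (HFBB) power, and lagged epoching.

The preprocessing chain for intracranial recordings is fixed:

    despike -> common_average_reference -> hfbb_power -> smooth_zero_phase
            -> epoch_lags

``despike`` removes large impulsive artifacts (samples beyond
median +/- k*IQR per electrode) and imputes them by cubic interpolation.
``common_average_reference`` (CAR) subtracts the instantaneous
across-electrode mean.  ``hfbb_power`` estimates 70-200 Hz broadband power
with six-cycle Morlet wavelets, skipping centers near the 60/120/180 Hz
line-noise harmonics, then log-transforms and z-scores each electrode over
the full recording.  ``smooth_zero_phase`` applies a unit-sum Hamming
kernel forward and backward (zero net phase).  ``epoch_lags`` averages the
smoothed power in a short window centered at word onset plus a temporal
lag, yielding one "brain embedding" (words x electrodes) per lag.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.ndimage import convolve1d
from scipy.signal.windows import hamming

logger = logging.getLogger(__name__)

__all__ = [
    "RawRecording",
    "HFBBSignal",
    "LagGrid",
    "BrainEmbedding",
    "despike",
    "common_average_reference",
    "hfbb_power",
    "smooth_zero_phase",
    "epoch_lags",
    "save_epochs",
    "load_epochs",
    "preprocess_raw",
]


@dataclass
class RawRecording:
    """Multielectrode voltage trace.

    Parameters
    ----------
    signal : ndarray, shape (n_electrodes, n_samples)
        Voltage in arbitrary units.
    fs_hz : float
        Sampling rate, Hz.
    electrode_meta : DataFrame
        One row per electrode with at least ``participant`` and ``region``
        columns (region in {"IFG", "precentral", "postcentral", "other"}).
    meta : dict
        Free-form provenance (generator seeds, injected artifact indices...).
    """

    signal: np.ndarray
    fs_hz: float
    electrode_meta: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (electrodes x samples)")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if len(self.electrode_meta) != self.signal.shape[0]:
            raise ValueError("electrode_meta rows must match electrode count")

    @property
    def n_electrodes(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    def save_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("signal", data=self.signal)
            f.create_dataset("fs_hz", data=float(self.fs_hz))
            meta = self.electrode_meta
            f.create_dataset(
                "electrode_meta/participant",
                data=np.asarray(meta["participant"].astype(str), dtype="S"),
            )
            f.create_dataset(
                "electrode_meta/region",
                data=np.asarray(meta["region"].astype(str), dtype="S"),
            )

    @classmethod
    def load_hdf5(cls, path) -> "RawRecording":
        import h5py

        with h5py.File(path, "r") as f:
            signal = f["signal"][()]
            fs = float(f["fs_hz"][()])
            meta = pd.DataFrame(
                {
                    "participant": [
                        s.decode() for s in f["electrode_meta/participant"][()]
                    ],
                    "region": [s.decode() for s in f["electrode_meta/region"][()]],
                }
            )
        return cls(signal=signal, fs_hz=fs, electrode_meta=meta)


@dataclass
class HFBBSignal:
    """High-frequency broadband power in log-z units, plus step provenance."""

    power: np.ndarray  # electrodes x samples
    fs_hz: float
    provenance: list = field(default_factory=list)
    electrode_meta: pd.DataFrame | None = None

    @property
    def n_electrodes(self) -> int:
        return self.power.shape[0]

    @property
    def n_samples(self) -> int:
        return self.power.shape[1]


@dataclass(frozen=True)
class LagGrid:
    """Regular grid of analysis lags relative to word onset.

    The default grid spans -4 s to +4 s in 25-ms steps (321 lags) with a
    200-ms averaging window at each lag.
    """

    start_ms: float = -4000.0
    stop_ms: float = 4000.0
    step_ms: float = 25.0
    window_ms: float = 200.0

    def __post_init__(self) -> None:
        span = self.stop_ms - self.start_ms
        n = span / self.step_ms
        if abs(n - round(n)) > 1e-9:
            raise ValueError("(stop_ms - start_ms) must be a multiple of step_ms")

    @property
    def lags_ms(self) -> np.ndarray:
        n = int(round((self.stop_ms - self.start_ms) / self.step_ms)) + 1
        return self.start_ms + self.step_ms * np.arange(n)

    def __len__(self) -> int:
        return len(self.lags_ms)

    def window_samples(self, fs_hz: float) -> int:
        # floor: 200 ms at 512 Hz -> 102 samples
        return int(np.floor(self.window_ms * fs_hz / 1000.0))


@dataclass
class BrainEmbedding:
    """Per-word electrode activity pattern at one lag.

    Each row is the vector of window-averaged HFBB power across electrodes
    for one word occurrence; the electrodes are the embedding dimensions.
    """

    matrix: np.ndarray  # words x electrodes
    lag_ms: float
    participant_scope: str = "pooled"
    event_index: np.ndarray | None = None  # row -> index into the event table

    @property
    def n_words(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_electrodes(self) -> int:
        return self.matrix.shape[1]


# ---------------------------------------------------------------------------
# pipeline steps
# ---------------------------------------------------------------------------


def despike(raw: RawRecording, k: float = 4.0) -> RawRecording:
    """Remove impulsive artifacts per electrode and impute them.

    Samples outside ``[median - k*IQR, median + k*IQR]`` (per electrode)
    are replaced by cubic interpolation through the retained samples;
    everything else is returned bit-identical.  The boolean flag matrix is
    stored in ``meta["despike_flags"]``.
    """
    x = raw.signal
    out = x.copy()
    flags = np.zeros_like(x, dtype=bool)
    idx = np.arange(x.shape[1])
    for e in range(x.shape[0]):
        med = np.median(x[e])
        q75, q25 = np.percentile(x[e], [75, 25])
        iqr = q75 - q25
        bad = np.abs(x[e] - med) > k * iqr
        if bad.all():
            raise ValueError(f"electrode {e} consists entirely of spikes")
        if bad.sum() == 0:
            continue
        good = ~bad
        if good.sum() < 4:
            raise ValueError(
                f"electrode {e} has fewer than 4 retained samples; "
                "cubic interpolation needs support"
            )
        spl = CubicSpline(idx[good], x[e, good], extrapolate=True)
        out[e, bad] = spl(idx[bad])
        flags[e] = bad
    meta = dict(raw.meta)
    meta["despike_flags"] = flags
    meta.setdefault("provenance", []).append(f"despike(k={k})")
    return replace(raw, signal=out, meta=meta)


def common_average_reference(raw: RawRecording) -> RawRecording:
    """Subtract the instantaneous across-electrode mean from every sample."""
    if raw.n_electrodes < 2:
        raise ValueError("common average reference needs at least 2 electrodes")
    out = raw.signal - raw.signal.mean(axis=0, keepdims=True)
    meta = dict(raw.meta)
    meta.setdefault("provenance", []).append("common_average_reference")
    return replace(raw, signal=out, meta=meta)


def _wavelet_centers(
    band_hz: tuple[float, float],
    spacing_hz: float,
    exclude_hz,
    exclusion_halfwidth_hz: float,
) -> np.ndarray:
    lo, hi = band_hz
    centers = np.arange(lo, hi + 1e-9, spacing_hz)
    keep = np.ones(len(centers), dtype=bool)
    for f0 in exclude_hz:
        keep &= np.abs(centers - f0) > exclusion_halfwidth_hz + 1e-9
    return centers[keep]


def hfbb_power(
    raw: RawRecording,
    band_hz: tuple[float, float] = (70.0, 200.0),
    n_cycles: float = 6.0,
    exclude_hz=(60.0, 120.0, 180.0),
    exclusion_halfwidth_hz: float = 5.0,
    spacing_hz: float = 5.0,
) -> HFBBSignal:
    """Six-cycle Morlet broadband power, log-transformed and z-scored.

    Wavelet centers span ``band_hz`` every ``spacing_hz``; centers within
    ``exclusion_halfwidth_hz`` of a line-noise harmonic are dropped.
    Linear power is averaged across the retained centers, then
    log-transformed, then z-scored per electrode over the full recording.
    """
    from mne.time_frequency import tfr_array_morlet

    if raw.fs_hz <= 2 * band_hz[1]:
        raise ValueError("sampling rate must exceed twice the upper band edge")
    centers = _wavelet_centers(band_hz, spacing_hz, exclude_hz, exclusion_halfwidth_hz)
    if len(centers) == 0:
        raise ValueError("no wavelet centers retained after line-noise exclusion")

    acc = np.zeros_like(raw.signal)
    data = raw.signal[np.newaxis]  # (1 epoch, electrodes, samples)
    for f0 in centers:
        p = tfr_array_morlet(
            data,
            sfreq=raw.fs_hz,
            freqs=[f0],
            n_cycles=n_cycles,
            output="power",
            verbose="error",
        )[0, :, 0, :]
        acc += p
    acc /= len(centers)
    logp = np.log(acc + 1e-300)
    mu = logp.mean(axis=1, keepdims=True)
    sd = logp.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (logp - mu) / sd
    prov = list(raw.meta.get("provenance", [])) + [
        f"hfbb_power(band={band_hz}, n_cycles={n_cycles}, "
        f"n_centers={len(centers)})"
    ]
    return HFBBSignal(
        power=z, fs_hz=raw.fs_hz, provenance=prov, electrode_meta=raw.electrode_meta
    )


def smooth_zero_phase(sig: HFBBSignal, kernel_ms: float = 50.0) -> HFBBSignal:
    """Two-pass (forward + backward) unit-sum Hamming smoothing.

    Zero net phase; reflect padding at the edges; output length equals
    input length.
    """
    n = int(round(kernel_ms * sig.fs_hz / 1000.0))
    n = max(n, 1)
    if n >= sig.n_samples:
        raise ValueError("smoothing kernel must be shorter than the recording")
    w = hamming(n)
    w = w / w.sum()
    fwd = convolve1d(sig.power, w, axis=-1, mode="reflect")
    back = convolve1d(fwd[:, ::-1], w, axis=-1, mode="reflect")[:, ::-1]
    return HFBBSignal(
        power=back,
        fs_hz=sig.fs_hz,
        provenance=sig.provenance + [f"smooth_zero_phase(kernel_ms={kernel_ms})"],
        electrode_meta=sig.electrode_meta,
    )


def epoch_lags(
    sig: HFBBSignal,
    events: pd.DataFrame,
    grid: LagGrid | None = None,
) -> dict[float, BrainEmbedding]:
    """Window-average the signal around each event at every lag.

    For each lag ``t`` the entry (word i, electrode e) is the mean of
    ``floor(window_ms * fs / 1000)`` samples centered at ``onset_i + t``
    (102 samples for a 200-ms window at 512 Hz).  Events whose window
    leaves the recording at any lag are dropped with a warning.

    Parameters
    ----------
    events : DataFrame with an ``onset_s`` column.

    Returns
    -------
    dict mapping lag (ms) to :class:`BrainEmbedding`; every embedding
    carries ``event_index`` giving the retained rows of ``events``.
    """
    if grid is None:
        grid = LagGrid()
    n_win = grid.window_samples(sig.fs_hz)
    if n_win < 1:
        raise ValueError("window shorter than one sample")
    onsets = np.asarray(events["onset_s"], dtype=float)
    lags = grid.lags_ms

    half = n_win // 2
    centers_min = np.round((onsets + lags.min() / 1000.0) * sig.fs_hz).astype(int)
    centers_max = np.round((onsets + lags.max() / 1000.0) * sig.fs_hz).astype(int)
    valid = (centers_min - half >= 0) & (centers_max - half + n_win <= sig.n_samples)
    n_dropped = int((~valid).sum())
    if n_dropped:
        warnings.warn(
            f"epoch_lags: dropped {n_dropped} events whose analysis window "
            "leaves the recording at some lag",
            stacklevel=2,
        )
    if valid.sum() == 0:
        raise ValueError("no events retained: all windows leave the recording")
    keep_idx = np.flatnonzero(valid)
    onsets = onsets[valid]

    out: dict[float, BrainEmbedding] = {}
    for lag in lags:
        centers = np.round((onsets + lag / 1000.0) * sig.fs_hz).astype(int)
        starts = centers - half
        # gather windows: words x electrodes
        mat = np.empty((len(onsets), sig.n_electrodes))
        for i, s in enumerate(starts):
            mat[i] = sig.power[:, s : s + n_win].mean(axis=1)
        out[float(lag)] = BrainEmbedding(
            matrix=mat, lag_ms=float(lag), event_index=keep_idx
        )
    return out


def save_epochs(epochs: dict[float, BrainEmbedding], path) -> None:
    """Write lagged brain embeddings to HDF5 (/lags, /matrix, /event_index)."""
    import h5py

    lags = np.array(sorted(epochs))
    mat = np.stack([epochs[lag].matrix for lag in lags])
    with h5py.File(path, "w") as f:
        f.create_dataset("lags", data=lags)
        f.create_dataset("matrix", data=mat)  # lag x word x electrode
        idx = epochs[lags[0]].event_index
        if idx is not None:
            f.create_dataset("event_index", data=idx)


def load_epochs(path) -> dict[float, BrainEmbedding]:
    import h5py

    with h5py.File(path, "r") as f:
        lags = f["lags"][()]
        mat = f["matrix"][()]
        idx = f["event_index"][()] if "event_index" in f else None
    return {
        float(lag): BrainEmbedding(matrix=mat[i], lag_ms=float(lag),
                                   event_index=idx)
        for i, lag in enumerate(lags)
    }


def preprocess_raw(
    raw: RawRecording,
    k: float = 4.0,
    band_hz: tuple[float, float] = (70.0, 200.0),
    n_cycles: float = 6.0,
    kernel_ms: float = 50.0,
) -> HFBBSignal:
    """Run the full fixed chain despike -> CAR -> HFBB -> smoothing."""
    r = despike(raw, k=k)
    r = common_average_reference(r)
    s = hfbb_power(r, band_hz=band_hz, n_cycles=n_cycles)
    return smooth_zero_phase(s, kernel_ms=kernel_ms)
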