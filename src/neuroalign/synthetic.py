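"""Synthetic token streams, embeddings and multielectrode recordings.

The generators produce data with a known ground-truth geometry so the
whole encoding/decoding pipeline can be exercised without access to
patient recordings:

* :func:`generate_stream` draws a token stream with Zipf-weighted word
  types at strictly increasing onsets (naturalistic speech has a heavy
  type-frequency tail and words separated by at least a short gap);
* :func:`generate_contextual_table` gives every occurrence of a type a
  unit vector lying inside a narrow cone around the type's base vector —
  the defining geometric property of contextual embeddings, whose
  per-type instances cluster tightly;
* :func:`generate_recording` synthesizes raw voltage whose 70-200 Hz
  amplitude envelope, time-locked to each word onset and shaped by a
  Gaussian response kernel peaking ~200 ms after onset, encodes a fixed
  linear map ``W @ embedding``; white noise, 60/120/180 Hz line noise and
  impulsive artifact spikes are added on top;
* :func:`oracle_brain_embeddings` bypasses signal synthesis and returns
  the analytic words-by-electrodes response at each lag, for fast tests
  and for validating the preprocessing chain end to end.

All randomness flows through one seeded generator per call; outputs are
byte-identical for identical seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import RawRecording

__all__ = [
    "GroundTruth",
    "TokenStream",
    "generate_stream",
    "generate_contextual_table",
    "generate_recording",
    "oracle_brain_embeddings",
    "oracle_decoder_input",
]

MIN_GAP_S = 0.100  # minimum inter-word onset gap


@dataclass
class GroundTruth:
    """Fixed generative parameters of a synthetic experiment.

    ``map_matrix`` (electrodes x embed_dim) is the linear map from word
    embedding to the per-electrode envelope response.  The lag-domain
    response kernel is a Gaussian with unit peak at ``peak_lag_ms``
    (SD ``width_ms``), plus an optional pre-onset Gaussian at
    ``pre_onset_lag_ms`` scaled by ``pre_onset_gain`` (< 1), emulating
    anticipatory activity before word onset.
    """

    map_matrix: np.ndarray
    peak_lag_ms: float = 200.0
    width_ms: float = 150.0
    pre_onset_gain: float = 0.0
    pre_onset_lag_ms: float = -500.0
    noise_sd: float = 0.0
    carrier_band: tuple[float, float] = (70.0, 200.0)
    line_noise_amps: dict = field(default_factory=dict)  # {60.:a, 120.:a, 180.:a}
    spike_rate: float = 0.0  # events per minute
    baseline: float = 1.0  # envelope floor

    def __post_init__(self) -> None:
        self.map_matrix = np.asarray(self.map_matrix, dtype=float)
        if not np.isfinite(self.map_matrix).all():
            raise ValueError("map_matrix must be finite")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.pre_onset_gain < 0:
            raise ValueError("pre_onset_gain must be >= 0")
        if self.pre_onset_gain >= 1:
            raise ValueError("pre_onset_gain must be < 1 so the main peak is max")

    @property
    def n_electrodes(self) -> int:
        return self.map_matrix.shape[0]

    @property
    def embed_dim(self) -> int:
        return self.map_matrix.shape[1]

    def kernel(self, lag_ms) -> np.ndarray:
        """Response kernel value at lag(s) in ms; unit peak at peak_lag_ms."""
        lag = np.asarray(lag_ms, dtype=float)
        main = np.exp(-0.5 * ((lag - self.peak_lag_ms) / self.width_ms) ** 2)
        pre = self.pre_onset_gain * np.exp(
            -0.5 * ((lag - self.pre_onset_lag_ms) / self.width_ms) ** 2
        )
        return main + pre


@dataclass
class TokenStream:
    """Ordered word events with type bookkeeping.

    ``events`` columns: token, onset_s, type_id, occurrence_idx,
    participant.  Onsets are strictly increasing and every type occurs at
    least once.
    """

    events: pd.DataFrame
    n_types: int
    zipf_s: float
    seed: int

    def __post_init__(self) -> None:
        onsets = self.events["onset_s"].to_numpy()
        if not (np.diff(onsets) > 0).all():
            raise ValueError("onsets must be strictly increasing")
        if self.events["type_id"].nunique() != self.n_types:
            raise ValueError("every type must occur at least once")

    def __len__(self) -> int:
        return len(self.events)

    def save_tsv(self, path) -> None:
        self.events.to_csv(path, sep="\t", index=False)


def generate_stream(
    n_types: int,
    n_tokens: int,
    duration_s: float,
    zipf_s: float = 1.1,
    seed: int = 0,
    participant: str = "synthetic",
) -> TokenStream:
    """Draw a token stream with Zipf-weighted types and ordered onsets.

    Every one of the ``n_types`` types occurs at least once (the first
    ``n_types`` draws cover each type once; the remainder are sampled with
    probability proportional to ``rank**-zipf_s``); the sequence order is
    then shuffled.  Onsets are uniform order statistics on
    ``(0, duration_s)`` with a minimum inter-word gap of 100 ms.
    """
    if n_types < 2:
        raise ValueError("need at least 2 word types")
    if n_tokens < n_types:
        raise ValueError("n_tokens < n_types: cannot cover all types")
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    slack = duration_s - (n_tokens + 1) * MIN_GAP_S
    if slack <= 0:
        raise ValueError("duration too short for n_tokens at the minimum gap")
    rng = np.random.default_rng(seed)

    ranks = np.arange(1, n_types + 1, dtype=float)
    probs = ranks**-zipf_s
    probs /= probs.sum()
    extra = rng.choice(n_types, size=n_tokens - n_types, p=probs)
    type_ids = np.concatenate([np.arange(n_types), extra])
    rng.shuffle(type_ids)

    u = np.sort(rng.uniform(0.0, slack, size=n_tokens))
    onsets = u + MIN_GAP_S * (1 + np.arange(n_tokens))

    width = len(str(n_types - 1))
    tokens = np.array([f"w{t:0{width}d}" for t in type_ids])
    occ = np.zeros(n_tokens, dtype=int)
    counts: dict[int, int] = {}
    for i, t in enumerate(type_ids):
        occ[i] = counts.get(t, 0)
        counts[t] = occ[i] + 1

    events = pd.DataFrame(
        {
            "token": tokens,
            "onset_s": onsets,
            "type_id": type_ids,
            "occurrence_idx": occ,
            "participant": participant,
        }
    )
    return TokenStream(events=events, n_types=n_types, zipf_s=zipf_s, seed=seed)


def generate_contextual_table(
    stream: TokenStream,
    embed_dim: int = 50,
    cone_angle_deg: float = 20.0,
    seed: int = 0,
):
    """Per-occurrence embeddings clustered in a cone per word type.

    Each type gets a random unit base vector; each occurrence's row is the
    base vector rotated by an angle drawn uniformly from
    ``[0, cone_angle_deg]`` in a random direction orthogonal to the base.
    With ``cone_angle_deg=0`` the table degenerates to a static (one
    vector per type) embedding.
    """
    from .embeddings import EmbeddingTable

    if embed_dim < 2:
        raise ValueError("embed_dim must be >= 2")
    if not 0 <= cone_angle_deg <= 90:
        raise ValueError("cone_angle_deg must be in [0, 90]")
    rng = np.random.default_rng(seed)

    base = rng.standard_normal((stream.n_types, embed_dim))
    base /= np.linalg.norm(base, axis=1, keepdims=True)

    type_ids = stream.events["type_id"].to_numpy()
    n = len(type_ids)
    rows = np.empty((n, embed_dim))
    angles = np.deg2rad(rng.uniform(0.0, cone_angle_deg, size=n))
    for i, t in enumerate(type_ids):
        b = base[t]
        u = rng.standard_normal(embed_dim)
        u -= (u @ b) * b
        nrm = np.linalg.norm(u)
        if nrm < 1e-12:  # essentially colinear draw; retry deterministic-ish
            u = np.roll(b, 1)
            u -= (u @ b) * b
            nrm = np.linalg.norm(u)
        u /= nrm
        rows[i] = np.cos(angles[i]) * b + np.sin(angles[i]) * u
    return EmbeddingTable(
        matrix=rows,
        kind="contextual",
        provenance={
            "source": "synthetic-cone",
            "cone_angle_deg": cone_angle_deg,
            "seed": seed,
        },
    )


def _tone_frequencies(rng, n: int, band, exclude=(60.0, 120.0, 180.0),
                      halfwidth: float = 7.0) -> np.ndarray:
    """Stratified random tone frequencies avoiding line-noise exclusions.

    The admissible band is split into ``n`` equal-measure slots and one
    frequency is drawn per slot (then shuffled across electrodes), so
    electrode carriers stay spectrally separated: close pairs would beat
    through the common average reference and contaminate the envelopes.
    """
    lo, hi = band
    segs = []
    edges = sorted([lo, hi] + [x for f0 in exclude
                               for x in (f0 - halfwidth, f0 + halfwidth)
                               if lo < x < hi])
    for a, b in zip(edges[:-1], edges[1:]):
        mid = (a + b) / 2
        if all(abs(mid - f0) > halfwidth for f0 in exclude):
            segs.append((a, b))
    total = sum(b - a for a, b in segs)
    u = (rng.permutation(n) + rng.uniform(0, 1, size=n)) / n * total
    out = np.empty(n)
    for i, x in enumerate(u):
        for a, b in segs:
            if x <= b - a:
                out[i] = a + x
                break
            x -= b - a
        else:
            out[i] = segs[-1][1]
    return out


def _envelope(
    stream: TokenStream, table, gt: GroundTruth, fs_hz: float, n_samples: int
) -> np.ndarray:
    """Noise-free amplitude envelope, electrodes x samples."""
    resp = table.matrix @ gt.map_matrix.T  # events x electrodes
    env = np.full((gt.n_electrodes, n_samples), gt.baseline)
    # kernel support: +/- 4 SD around both Gaussians
    lo_ms = min(gt.peak_lag_ms, gt.pre_onset_lag_ms if gt.pre_onset_gain else gt.peak_lag_ms)
    hi_ms = max(gt.peak_lag_ms, gt.pre_onset_lag_ms if gt.pre_onset_gain else gt.peak_lag_ms)
    lo = int(np.floor((lo_ms - 4 * gt.width_ms) * fs_hz / 1000.0))
    hi = int(np.ceil((hi_ms + 4 * gt.width_ms) * fs_hz / 1000.0))
    rel = np.arange(lo, hi + 1)
    kern = gt.kernel(rel * 1000.0 / fs_hz)
    onsets = stream.events["onset_s"].to_numpy()
    for i, onset in enumerate(onsets):
        c = int(round(onset * fs_hz))
        a, b = c + lo, c + hi + 1
        ka, kb = 0, len(rel)
        if a < 0:
            ka = -a
            a = 0
        if b > n_samples:
            kb -= b - n_samples
            b = n_samples
        if a >= b:
            continue
        env[:, a:b] += np.outer(resp[i], kern[ka:kb])
    return env


def generate_recording(
    stream: TokenStream,
    table,
    gt: GroundTruth,
    fs_hz: float = 512.0,
    duration_s: float | None = None,
    seed: int = 0,
    carrier: str = "tone",
    n_carrier: int = 60,
    regions=None,
) -> RawRecording:
    """Synthesize raw voltage whose HFBB envelope encodes ``W @ embedding``.

    The band-limited carrier is amplitude-modulated by
    ``baseline + kernel(t - onset) * (W @ x)`` (additive superposition for
    overlapping responses).  Two carrier modes:

    * ``"tone"`` (default): one sinusoid per electrode at a random
      in-band frequency (away from the line-noise exclusion zones) with
      a random phase.  Its envelope is deterministic, so the wavelet
      power average tracks the modulation exactly.
    * ``"multitone"``: a sum of ``n_carrier`` random-frequency,
      random-phase sinusoids.  Statistically closer to broadband neural
      power but its envelope carries Rayleigh-like fading that acts as
      multiplicative noise on the word responses.

    White noise, line-noise sinusoids and impulsive spikes (indices
    recorded in ``meta["spike_samples"]``) are added afterwards.
    """
    if fs_hz <= 2 * gt.carrier_band[1]:
        raise ValueError("fs_hz must exceed twice the upper carrier frequency")
    rng = np.random.default_rng(seed)
    onsets = stream.events["onset_s"].to_numpy()
    if duration_s is None:
        duration_s = float(onsets[-1] + 2.0)
    n_samples = int(round(duration_s * fs_hz))
    t = np.arange(n_samples) / fs_hz

    env = _envelope(stream, table, gt, fs_hz, n_samples)
    env = np.clip(env, 0.0, None)  # physical envelope is non-negative

    E = gt.n_electrodes
    sig = np.empty((E, n_samples))
    if carrier == "tone":
        freqs = _tone_frequencies(rng, E, gt.carrier_band)
        phases = rng.uniform(0, 2 * np.pi, size=E)
        for e in range(E):
            sig[e] = env[e] * (
                np.sqrt(2.0) * np.sin(2 * np.pi * freqs[e] * t + phases[e])
            )
    elif carrier == "multitone":
        freqs = rng.uniform(*gt.carrier_band, size=(E, n_carrier))
        phases = rng.uniform(0, 2 * np.pi, size=(E, n_carrier))
        for e in range(E):
            c = np.zeros(n_samples)
            for j in range(n_carrier):
                c += np.sin(2 * np.pi * freqs[e, j] * t + phases[e, j])
            c /= np.sqrt(n_carrier / 2.0)  # unit RMS
            sig[e] = env[e] * c
    else:
        raise ValueError("carrier must be 'tone' or 'multitone'")

    if gt.noise_sd > 0:
        sig += gt.noise_sd * rng.standard_normal(sig.shape)
    for f0, amp in gt.line_noise_amps.items():
        if amp:
            phase = rng.uniform(0, 2 * np.pi, size=(E, 1))
            sig += amp * np.sin(2 * np.pi * float(f0) * t[np.newaxis] + phase)

    spike_samples: list[tuple[int, int]] = []
    if gt.spike_rate > 0:
        n_spikes = rng.poisson(gt.spike_rate * duration_s / 60.0)
        amp = 20.0 * max(np.abs(sig).max(), 1.0)
        for _ in range(n_spikes):
            e = int(rng.integers(E))
            s = int(rng.integers(n_samples))
            sig[e, s] += amp * rng.choice([-1.0, 1.0])
            spike_samples.append((e, s))

    if regions is None:
        regions = ["IFG"] * E
    meta = pd.DataFrame(
        {"participant": ["synthetic"] * E, "region": list(regions)}
    )
    return RawRecording(
        signal=sig,
        fs_hz=fs_hz,
        electrode_meta=meta,
        meta={"seed": seed, "spike_samples": spike_samples},
    )


def oracle_brain_embeddings(
    stream: TokenStream,
    table,
    gt: GroundTruth,
    lag_grid,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> dict[float, np.ndarray]:
    """Analytic words-by-electrodes response at each lag, bypassing signals.

    At lag ``t`` the matrix is ``kernel(t) * (X @ W.T) + noise``; exact for
    a fixed seed.  ``lag_grid`` may be a :class:`~neuroalign.preprocess.LagGrid`
    or any iterable of lags in ms.
    """
    rng = np.random.default_rng(seed)
    lags = getattr(lag_grid, "lags_ms", None)
    if lags is None:
        lags = np.asarray(list(lag_grid), dtype=float)
    resp = table.matrix @ gt.map_matrix.T  # events x electrodes
    out: dict[float, np.ndarray] = {}
    for lag in lags:
        m = gt.kernel(lag) * resp
        if noise_sd > 0:
            m = m + noise_sd * rng.standard_normal(m.shape)
        out[float(lag)] = m
    return out


def oracle_decoder_input(
    stream: TokenStream,
    table,
    gt: GroundTruth,
    lag_ms: float = 200.0,
    n_bins: int = 10,
    bin_ms: float = 62.5,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Analytic decoder tensor (words x electrodes x bins) at one lag.

    Bin ``b`` is the kernel evaluated at the bin center of a 625-ms span
    centered on ``onset + lag_ms`` times ``X @ W.T``, plus optional noise —
    the analytic counterpart of binning the synthetic HFBB signal.
    """
    rng = np.random.default_rng(seed)
    resp = table.matrix @ gt.map_matrix.T  # events x electrodes
    span = n_bins * bin_ms
    centers = lag_ms - span / 2 + bin_ms * (0.5 + np.arange(n_bins))
    k = gt.kernel(centers)  # (n_bins,)
    tensor = resp[:, :, np.newaxis] * k[np.newaxis, np.newaxis, :]
    if noise_sd > 0:
        tensor = tensor + noise_sd * rng.standard_normal(tensor.shape)
    return tensor
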