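"""End-to-end orchestration: simulate -> preprocess -> embed -> fold ->
encode -> decode -> stats -> report, from a single TOML config.

Each run writes into one immutable directory containing every stage's
output plus a manifest (config hash, seeds, package version) sufficient
to reproduce deterministic stages byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run", "report"]

_STAGES = ("simulate", "preprocess", "embed", "fold", "encode", "decode", "stats")


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run.

    Every stage reads only its own sub-dictionary; all seeds derive from
    the single top-level ``seed``.
    """

    seed: int = 0
    stages: tuple = _STAGES
    region: str | None = None  # electrode filter: IFG | precentral | ...
    simulate: dict = field(default_factory=dict)
    lag_grid: dict = field(default_factory=dict)
    folds: dict = field(default_factory=dict)
    embedding: dict = field(default_factory=dict)
    encoding: dict = field(default_factory=dict)
    decoding: dict = field(default_factory=dict)
    stats: dict = field(default_factory=dict)
    paths: dict = field(default_factory=dict)  # inputs when simulate is off

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        self.seed = int(self.seed)

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as f:
            cfg = tomllib.load(f)
        if "stages" in cfg:
            cfg["stages"] = tuple(cfg["stages"])
        return cls(**cfg)

    def digest(self) -> str:
        def default(o):
            return sorted(o) if isinstance(o, (set, frozenset)) else str(o)

        payload = json.dumps(self.__dict__, sort_keys=True, default=default)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _simulate(cfg: RunConfig, outdir: Path):
    from . import synthetic

    p = {
        "n_types": 60,
        "n_tokens": 150,
        "duration_s": 120.0,
        "zipf_s": 1.1,
        "embed_dim": 10,
        "cone_angle_deg": 20.0,
        "n_electrodes": 12,
        "fs_hz": 512.0,
        "noise_sd": 0.0,
        "spike_rate": 0.0,
        "line_amp": 0.0,
        "response_scale": 0.3,
        **cfg.simulate,
    }
    rng = np.random.default_rng(cfg.seed)
    stream = synthetic.generate_stream(
        p["n_types"], p["n_tokens"], p["duration_s"], p["zipf_s"], seed=cfg.seed
    )
    table = synthetic.generate_contextual_table(
        stream, p["embed_dim"], p["cone_angle_deg"], seed=cfg.seed + 1
    )
    W = p["response_scale"] * rng.standard_normal(
        (p["n_electrodes"], p["embed_dim"])
    ) / np.sqrt(p["embed_dim"])
    gt = synthetic.GroundTruth(
        map_matrix=W,
        noise_sd=p["noise_sd"],
        spike_rate=p["spike_rate"],
        line_noise_amps={60.0: p["line_amp"], 120.0: p["line_amp"], 180.0: p["line_amp"]},
    )
    rec = synthetic.generate_recording(
        stream, table, gt, fs_hz=p["fs_hz"], seed=cfg.seed + 2,
        regions=p.get("regions"),
    )
    stream.save_tsv(outdir / "events.tsv")
    from .embeddings import save_table

    save_table(table, outdir / "embeddings.tsv")
    rec.save_hdf5(outdir / "recording.h5")
    return {"stream": stream, "table": table, "gt": gt, "recording": rec}


def _load_inputs(cfg: RunConfig):
    from .embeddings import load_table
    from .preprocess import RawRecording
    from .synthetic import TokenStream

    paths = cfg.paths
    for key in ("events", "embeddings", "recording"):
        if key not in paths:
            raise FileNotFoundError(
                f"pipeline input '{key}' not configured and simulate stage disabled"
            )
        if not Path(paths[key]).exists():
            raise FileNotFoundError(f"pipeline input '{key}': {paths[key]} not found")
    events = pd.read_csv(paths["events"], sep="\t")
    stream = TokenStream(
        events=events,
        n_types=events["type_id"].nunique(),
        zipf_s=float("nan"),
        seed=-1,
    )
    table = load_table(
        paths["embeddings"], kind="contextual", expected_rows=len(events)
    )
    rec = RawRecording.load_hdf5(paths["recording"])
    return {"stream": stream, "table": table, "recording": rec}


def run(config: RunConfig, outdir) -> Path:
    """Execute the configured stages; returns the run directory.

    A stage failure aborts the run with the failing stage named.  The
    manifest records the config hash and seeds for reproducibility.
    """
    from . import decoding, encoding, folds as folds_mod, preprocess

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    state: dict = {}
    done = []
    current = "inputs"
    try:
        current = "simulate"
        if "simulate" in config.stages:
            state.update(_simulate(config, outdir))
            done.append("simulate")
        else:
            state.update(_load_inputs(config))

        grid = preprocess.LagGrid(**config.lag_grid) if config.lag_grid else (
            preprocess.LagGrid(start_ms=-400, stop_ms=600, step_ms=100)
        )

        current = "preprocess"
        if "preprocess" in config.stages:
            rec = state["recording"]
            if config.region is not None:
                mask = (rec.electrode_meta["region"] == config.region).to_numpy()
                if mask.sum() == 0:
                    raise ValueError(f"no electrodes in region {config.region!r}")
                rec = preprocess.RawRecording(
                    signal=rec.signal[mask],
                    fs_hz=rec.fs_hz,
                    electrode_meta=rec.electrode_meta[mask].reset_index(drop=True),
                    meta=rec.meta,
                )
            sig = preprocess.preprocess_raw(rec)
            state["hfbb"] = sig
            done.append("preprocess")

        current = "fold"
        if "fold" in config.stages:
            sel = folds_mod.select_unique_instances(state["stream"], seed=config.seed)
            spec = folds_mod.make_folds(
                sel, k=int(config.folds.get("k", 10)), seed=config.seed
            )
            spec.to_tsv(outdir / "folds.tsv")
            state["folds"] = spec
            done.append("fold")

        current = "embed"
        if "embed" in config.stages:
            from .embeddings import pca_reduce

            table = state["table"]
            n_comp = config.embedding.get("pca_components")
            if n_comp:
                table = pca_reduce(table, n_components=int(n_comp))
            state["table_reduced"] = table
            done.append("embed")
        else:
            state["table_reduced"] = state["table"]

        current = "encode"
        if "encode" in config.stages:
            spec = state["folds"]
            sel_idx = spec.events["event_idx"].to_numpy()
            epochs = preprocess.epoch_lags(
                state["hfbb"], spec.events, grid
            )
            # epoch_lags may drop events; restrict folds/table accordingly
            kept = next(iter(epochs.values())).event_index
            if len(kept) != spec.n_words:
                spec = folds_mod.make_folds(
                    spec.events.iloc[kept], k=spec.k, seed=config.seed
                )
                sel_idx = spec.events["event_idx"].to_numpy()
                epochs = preprocess.epoch_lags(state["hfbb"], spec.events, grid)
            table_sel = state["table_reduced"].take(sel_idx)
            model = encoding.ZeroShotEncodingModel(table_sel, epochs, spec)
            res = model.fit(
                variants=tuple(config.encoding.get("variants", ("actual",))),
                n_shuffles=int(config.encoding.get("n_shuffles", 10)),
                seed=config.seed,
            )
            res.to_tsv(outdir / "encoding.tsv", outdir / "encoding_summary.tsv")
            state["encoding"] = res
            state["folds_used"] = spec
            state["table_selected"] = table_sel
            done.append("encode")

        current = "decode"
        if "decode" in config.stages:
            spec = state.get("folds_used", state["folds"])
            lag = float(config.decoding.get("lag_ms", 200.0))
            tensor, kept = decoding.bin_signal(state["hfbb"], spec.events, lag)
            if len(kept) != spec.n_words:
                raise ValueError("decoder windows leave the recording; shorten lags")
            table_sel = state.get("table_selected")
            if table_sel is None:
                table_sel = state["table_reduced"].take(
                    spec.events["event_idx"].to_numpy()
                )
            dcfg = decoding.DecoderConfig(
                ensemble_size=int(config.decoding.get("ensemble_size", 6))
            )
            dmodel = decoding.ZeroShotDecodingModel(
                tensor, table_sel.matrix, spec, config=dcfg
            )
            dres = dmodel.fit(
                seed=config.seed,
                test_folds=config.decoding.get("test_folds"),
                variants=tuple(config.decoding.get("variants", ("actual",))),
            )
            dres.to_tsv(outdir / "decoding.tsv")
            state["decoding"] = dres
            done.append("decode")

        current = "stats"
        if "stats" in config.stages and "encoding" in state:
            sig = state["encoding"].significance(
                n_boot=int(config.stats.get("n_boot", 5000)),
                q=float(config.stats.get("q", 0.01)),
                seed=config.seed,
            )
            lags = np.sort(state["encoding"].scores["lag_ms"].unique())
            pd.DataFrame(
                {"lag_ms": lags, "p": sig.pvals, "significant": sig.significant}
            ).to_csv(outdir / "stats.tsv", sep="\t", index=False)
            state["stats"] = sig
            done.append("stats")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{current}' failed: {exc}") from exc

    manifest = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "stages": done,
        "package": _version(),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir


def _version() -> str:
    from importlib.metadata import version

    try:
        return version("neuroalign")
    except Exception:
        return "unknown"


def report(run_dir, make_plots: bool = True) -> pd.DataFrame:
    """Assemble per-lag summary curves (mean +/- SE) with significance marks.

    Returns the merged summary table; with ``make_plots`` a PNG of the
    per-lag curves is written next to it.  An incomplete run yields a
    partial report with warnings.
    """
    import warnings

    run_dir = Path(run_dir)
    summary_path = run_dir / "encoding_summary.tsv"
    if not summary_path.exists():
        warnings.warn("report: no encoding summary found; empty report", stacklevel=2)
        out = pd.DataFrame(columns=["lag_ms", "variant", "mean_r", "n", "se"])
        out.to_csv(run_dir / "report.tsv", sep="\t", index=False)
        return out
    summary = pd.read_csv(summary_path, sep="\t")
    stats_path = run_dir / "stats.tsv"
    if stats_path.exists():
        st = pd.read_csv(stats_path, sep="\t")
        summary = summary.merge(st, on="lag_ms", how="left")
    else:
        warnings.warn("report: stats stage output missing", stacklevel=2)
    summary.to_csv(run_dir / "report.tsv", sep="\t", index=False)

    if make_plots:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, 4))
        for v, sv in summary.groupby("variant"):
            ax.plot(sv["lag_ms"], sv["mean_r"], label=v)
            ax.fill_between(
                sv["lag_ms"], sv["mean_r"] - sv["se"], sv["mean_r"] + sv["se"],
                alpha=0.3,
            )
        if "significant" in summary.columns:
            sig = summary[(summary["variant"] == "actual") & summary["significant"].fillna(False)]
            ax.plot(sig["lag_ms"], np.full(len(sig), summary["mean_r"].min() - 0.02),
                    "k*", ms=5, label="significant")
        ax.axvline(0, color="k", lw=0.5)
        ax.set_xlabel("lag (ms)")
        ax.set_ylabel("mean r")
        ax.legend()
        fig.tight_layout()
        fig.savefig(run_dir / "report.png", dpi=120)
        plt.close(fig)
    return summary
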