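"""End-to-end orchestration of the analysis stages.

``run_pipeline`` executes design -> simulate -> quantify -> stats ->
population coding -> densify/decode (and optionally the encoding models) in
dependency order, writing tidy CSVs, a JSON manifest with per-file
checksums and row counts, and a log.  Identical configurations (including
seeds) produce byte-identical CSV outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ctxfx, popcode, stats, synthgen
from .io import save_recording, write_csv
from .stimdesign import SoundLibrary, design_sequences, validate_sequences
from .synthgen import SimConfig

__all__ = ["RunConfig", "run_pipeline", "report"]

log = logging.getLogger("ctxcode")


@dataclass
class RunConfig:
    """Seeds, shuffle counts and thresholds for one reproducible run."""

    seed: int = 0
    n_sounds: int = 4
    n_neurons: int = 12
    n_reps: int = 20
    effect_sparsity: float = 0.1
    noise_model: str = "poisson"
    n_shuffles: int = 11000
    family_alpha: float = 0.05
    vocal_ids: tuple = ()
    decode_bins: tuple = (0, 1, 2, 3, 4, 5)
    run_encoding: bool = False
    stages: tuple = ("design", "simulate", "quantify", "stats",
                     "popcode", "densify")

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self))

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text)
        for key in ("vocal_ids", "decode_bins", "stages"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Run the configured stages; returns the run directory.

    Aborts on stage failure after persisting a partial manifest naming the
    failed stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": asdict(config), "stages": {}, "files": {}}
    (out / "config.yaml").write_text(config.to_yaml())
    handler = logging.FileHandler(out / "run.log")
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    def record(stage, files, rows=None):
        manifest["stages"][stage] = {"rows": rows, "time": time.time()}
        for f in files:
            p = out / f
            manifest["files"][f] = {"sha256": _checksum(p),
                                    "bytes": p.stat().st_size}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    try:
        # design
        seqset = design_sequences(config.n_sounds, seed=config.seed)
        rep = validate_sequences(seqset)
        assert rep["valid"], rep
        (out / "sequences.json").write_text(seqset.to_json())
        record("design", ["sequences.json"], rows=len(seqset.sequences))
        log.info("design: %d sequences", len(seqset.sequences))

        # simulate
        sim = SimConfig(n_neurons=config.n_neurons, n_reps=config.n_reps,
                        n_sounds=config.n_sounds,
                        effect_sparsity=config.effect_sparsity,
                        noise_model=config.noise_model, seed=config.seed)
        rec, gt = synthgen.simulate_population(sim)
        save_recording(rec, out / "recording.h5")
        write_csv(gt.effect_map, out / "ground_truth.csv")
        record("simulate", ["ground_truth.csv"], rows=len(gt.effect_map))

        # quantify
        effects = ctxfx.quantify_recording(rec, n_shuffles=config.n_shuffles,
                                           family_alpha=config.family_alpha,
                                           seed=config.seed)
        write_csv(effects, out / "effects.csv")
        record("quantify", ["effects.csv"], rows=len(effects))
        log.info("quantify: %d/%d significant", int(effects.significant.sum()),
                 len(effects))

        # stats
        lib = SoundLibrary(config.n_sounds,
                           {i: True for i in config.vocal_ids})
        table = stats.build_category_table(effects[effects.significant], lib)
        if len(table) and table.similarity.nunique() >= 2:
            reg = stats.category_regression(table)
            write_csv(reg, out / "category_regression.csv")
            record("stats", ["category_regression.csv"], rows=len(reg))
        else:
            write_csv(pd.DataFrame(), out / "category_regression.csv")
            record("stats", ["category_regression.csv"], rows=0)

        # population coding
        n_inst = config.n_sounds ** 2 * (config.n_sounds + 1) // 2
        cov = popcode.neuron_coverage(effects, n_inst)
        cov_summary = popcode.site_coverage_summary(effects, n_inst)
        write_csv(cov, out / "coverage.csv")
        write_csv(cov_summary, out / "coverage_summary.csv")
        record("popcode", ["coverage.csv", "coverage_summary.csv"],
               rows=len(cov))

        # densify + decode
        z, _ = ctxfx.zscore_normalize(rec)
        seg = synthgen.segment_instances(rec, data=z)
        grid = seg.grid()
        dense = popcode.densify(grid)
        bins = np.array(config.decode_bins)
        rows = []
        for label in ("context", "probe"):
            for name, data in (("original", grid), ("dense", dense.r_hat)):
                dt = popcode.decode_timecourse(data, label, seed=config.seed,
                                              bins=bins)
                for b, a in zip(dt.bins, dt.accuracy):
                    rows.append({"labels": label, "data": name, "bin": int(b),
                                 "accuracy": a, "chance": dt.chance})
        write_csv(pd.DataFrame(rows), out / "decoding.csv")
        record("densify", ["decoding.csv"], rows=len(rows))

        if config.run_encoding:
            from . import encmodel
            specs, resp = encmodel.prepare_encoding_inputs(rec, seed=config.seed)
            fits = [encmodel.fit_variants(specs, resp, i,
                                          scramble_seed=config.seed + i)
                    for i in range(min(rec.n_neurons, 10))]
            comp = encmodel.compare_models(fits)
            write_csv(comp, out / "model_comparison.csv")
            record("encode", ["model_comparison.csv"], rows=len(comp))
    except Exception as exc:  # persist partial manifest, then re-raise
        manifest["failed_stage"] = {
            "error": repr(exc),
            "completed": list(manifest["stages"]),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
    return out


def report(run_dir: str | Path) -> Path:
    """Summary document (markdown + figures) for a completed run."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run = Path(run_dir)
    effects = pd.read_csv(run / "effects.csv")
    lines = ["# Context-effect analysis summary", ""]
    n_sig = int(effects.significant.sum())
    lines.append(f"- contextual instances tested: {len(effects)}")
    lines.append(f"- significant instances: {n_sig}"
                 f" ({100 * n_sig / max(len(effects), 1):.2f}%)")
    if n_sig == 0:
        lines.append("- no significant instances: downstream panels omitted")
    cov_path = run / "coverage_summary.csv"
    if cov_path.exists():
        cs = pd.read_csv(cov_path)
        for r in cs.itertuples():
            lines.append(f"- coverage ({r.entity}): {r.coverage_pct:.2f}%")
    dec_path = run / "decoding.csv"
    if dec_path.exists():
        dec = pd.read_csv(dec_path)
        fig, ax = plt.subplots(figsize=(5, 3))
        for (lab, data), d in dec.groupby(["labels", "data"]):
            ax.plot(d.bin * 0.05, d.accuracy, label=f"{lab}/{data}")
        if len(dec):
            for ch in dec.chance.unique():
                ax.axhline(ch, ls=":", c="gray", lw=0.8)
        ax.set(xlabel="time in probe (s)", ylabel="accuracy")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(run / "decoding.png", dpi=120)
        plt.close(fig)
        for (lab, data), d in dec.groupby(["labels", "data"]):
            lines.append(f"- decoding {lab} ({data}): "
                         f"mean accuracy {d.accuracy.mean():.3f} "
                         f"(chance {d.chance.iloc[0]:.3f})")
    sig_df = effects[effects.significant]
    if len(sig_df):
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.scatter(sig_df.duration_ms, sig_df.amplitude_zs, s=8, alpha=0.6)
        ax.set(xlabel="duration (ms)", ylabel="amplitude (Z-score s)")
        fig.tight_layout()
        fig.savefig(run / "amplitude_duration.png", dpi=120)
        plt.close(fig)
    out = run / "report.md"
    out.write_text("\n".join(lines) + "\n")
    return out
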