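"""End-to-end pipeline: simulate -> preprocess -> train -> evaluate.

A single YAML-style mapping configures every stage; unknown keys are
rejected up front, and each stage's sub-configuration is validated before
any computation starts.  One global seed fans out to per-stage sub-seeds
through ``numpy.random.SeedSequence([global_seed, stage_index])``, so a
stage can be rerun independently yet reproducibly.  Every artifact is
listed in a manifest with its SHA-256 hash, giving a provenance chain
from the report back to the simulator configuration.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .evaluate import evaluate, save_plots
from .io import (
    read_records_hdf5, write_records_hdf5, write_processed_hdf5,
    read_processed_hdf5, write_predictions_csv, write_record_csv,
)
from .model import ModelConfig, MSFEConfig, SEConfig, MSAResNet, predict, save_checkpoint
from .preprocess import FilterSpec, preprocess_records, screening_summary
from .synth import SimConfig, generate_dataset
from .train import TrainConfig, split_dataset, train, inputs_to_arrays

__all__ = ["PipelineConfig", "run_all", "fixture_suite", "stage_seed"]

_STAGES = ("simulate", "preprocess", "train", "evaluate")

_SIM_KEYS = {
    "n_records", "preset", "duration_s", "fs", "hr_bpm", "sbp", "dbp",
    "drift_amp", "drift_freq", "powerline_amp", "powerline_freq",
    "noise_sd", "dicrotic_strength", "jitter_frac",
}
_PRE_KEYS = {
    "window_s", "stride_s", "filter_order", "low_hz", "high_hz", "filter_mode",
    "sbp_max", "dbp_min", "skew_min", "ac_threshold",
}
_MODEL_KEYS = {
    "width_multiplier", "blocks_per_stage", "stage_channels", "regular_kernels",
    "large_kernel", "branch_channels", "se_reduction",
}
_TRAIN_KEYS = {
    "loss", "delta", "batch_size", "epochs", "lr0", "eta_min", "momentum",
    "weight_decay", "split", "split_unit",
}
_EVAL_KEYS = {"sd_as_printed", "plots"}


def stage_seed(global_seed: int, stage_index: int) -> int:
    """Deterministic per-stage sub-seed (< 2**31)."""
    ss = np.random.SeedSequence([int(global_seed), int(stage_index)])
    return int(ss.generate_state(1)[0] % (2**31))


class PipelineConfig:
    """Validated nested configuration for :func:`run_all`."""

    def __init__(self, raw: dict):
        if not isinstance(raw, dict):
            raise ValueError("pipeline config must be a mapping")
        known_top = {"seed", "out_dir", "sim", "preprocess", "model", "train", "evaluate"}
        unknown = set(raw) - known_top
        if unknown:
            raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
        self.seed = int(raw.get("seed", 0))
        self.out_dir = raw.get("out_dir", "ppgbp_run")
        self.sim = dict(raw.get("sim", {}))
        self.pre = dict(raw.get("preprocess", {}))
        self.model = dict(raw.get("model", {}))
        self.train = dict(raw.get("train", {}))
        self.eval = dict(raw.get("evaluate", {}))
        for name, section, allowed in (
            ("sim", self.sim, _SIM_KEYS),
            ("preprocess", self.pre, _PRE_KEYS),
            ("model", self.model, _MODEL_KEYS),
            ("train", self.train, _TRAIN_KEYS),
            ("evaluate", self.eval, _EVAL_KEYS),
        ):
            unknown = set(section) - allowed
            if unknown:
                raise ValueError(f"unknown keys in '{name}' section: {sorted(unknown)}")
        # build (and thereby validate) every stage configuration up front
        self.n_records = int(self.sim.get("n_records", 200))
        self.preset = self.sim.get("preset", "uniform")
        sim_fields = {k: v for k, v in self.sim.items() if k not in ("n_records", "preset")}
        self.base_sim = SimConfig(**sim_fields)
        self.base_sim.validate()
        self.filter_spec = FilterSpec(
            order=int(self.pre.get("filter_order", 4)),
            low_hz=float(self.pre.get("low_hz", 0.5)),
            high_hz=float(self.pre.get("high_hz", 8.0)),
            mode=self.pre.get("filter_mode", "zero-phase"),
        )
        self.filter_spec.validate(self.base_sim.fs)
        m = self.model
        first_stage = tuple(m.get("stage_channels", (64, 128, 256, 512)))[0]
        self.model_cfg = ModelConfig(
            msfe=MSFEConfig(
                regular_kernels=tuple(m.get("regular_kernels", (3, 5, 7))),
                large_kernel=int(m.get("large_kernel", 13)),
                branch_channels=int(m.get("branch_channels", 16)),
                out_channels=first_stage,
            ),
            se=SEConfig(reduction=int(m.get("se_reduction", 16))),
            blocks_per_stage=tuple(m.get("blocks_per_stage", (3, 4, 6, 3))),
            stage_channels=tuple(m.get("stage_channels", (64, 128, 256, 512))),
            width_multiplier=float(m.get("width_multiplier", 1.0)),
        )
        self.model_cfg.validate()
        t = self.train
        self.train_cfg = TrainConfig(
            loss=t.get("loss", "huber"),
            delta=float(t.get("delta", 1.0)),
            batch_size=int(t.get("batch_size", 1024)),
            epochs=int(t.get("epochs", 120)),
            lr0=float(t.get("lr0", 0.001)),
            eta_min=float(t.get("eta_min", 0.0)),
            momentum=float(t.get("momentum", 0.9)),
            weight_decay=float(t.get("weight_decay", 0.0)),
            split=tuple(t.get("split", (0.7, 0.1, 0.2))),
            split_unit=t.get("split_unit", "segment"),
        )
        self.train_cfg.validate()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(cfg: PipelineConfig, out_dir=None, log=print) -> dict:
    """Run the four stages, writing artifacts and a provenance manifest.

    Returns the manifest dictionary.  Identical configurations produce
    identical report metrics (all randomness is derived from the global
    seed).
    """
    out = Path(out_dir if out_dir is not None else cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package_version": __version__,
        "global_seed": cfg.seed,
        "stage_seeds": {s: stage_seed(cfg.seed, i) for i, s in enumerate(_STAGES)},
        "artifacts": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    def register(name: str, path: Path, depends_on=()):
        manifest["artifacts"][name] = {
            "path": str(path),
            "sha256": _sha256(path),
            "depends_on": list(depends_on),
        }

    # -- simulate -----------------------------------------------------------
    log("[simulate] generating records")
    records = generate_dataset(
        cfg.n_records, bp_sampler=cfg.preset, base_cfg=cfg.base_sim,
        seed=manifest["stage_seeds"]["simulate"],
    )
    records_path = out / "records.h5"
    write_records_hdf5(records, records_path)
    register("records", records_path)

    # -- preprocess ---------------------------------------------------------
    log("[preprocess] filtering, segmenting, screening")
    inputs, reports = preprocess_records(
        records,
        window_s=float(cfg.pre.get("window_s", 3.0)),
        stride_s=cfg.pre.get("stride_s"),
        filter_spec=cfg.filter_spec,
        sbp_max=float(cfg.pre.get("sbp_max", 180.0)),
        dbp_min=float(cfg.pre.get("dbp_min", 50.0)),
        skew_min=float(cfg.pre.get("skew_min", 0.0)),
        ac_threshold=float(cfg.pre.get("ac_threshold", 0.6)),
    )
    if not inputs:
        raise RuntimeError("preprocessing kept no segments; check the sim config")
    summary = screening_summary(reports)
    processed_path = out / "processed.h5"
    write_processed_hdf5(inputs, processed_path, screening_summary=summary)
    register("processed", processed_path, depends_on=["records"])
    screening_path = out / "screening.json"
    screening_path.write_text(json.dumps(summary, indent=2))
    register("screening_report", screening_path, depends_on=["processed"])
    log(f"[preprocess] kept {summary['kept']}/{summary['total']} segments")

    # -- train --------------------------------------------------------------
    log("[train] optimizing the model")
    X, y, rid = inputs_to_arrays(inputs)
    tcfg = cfg.train_cfg
    tcfg.seed = manifest["stage_seeds"]["train"]
    model = MSAResNet(cfg.model_cfg, seed=tcfg.seed)
    model.head.b.data[:] = y.mean(axis=0).astype(model.dtype)
    model, hist = train(model, X, y, tcfg, record_ids=rid, log=log)
    ckpt_path = out / "checkpoint.npz"
    save_checkpoint(ckpt_path, model, extra={"train_config": asdict(tcfg)})
    register("checkpoint", ckpt_path, depends_on=["processed"])
    hist_path = out / "history.csv"
    hist.to_csv(hist_path)
    register("history", hist_path, depends_on=["checkpoint"])

    # -- evaluate -----------------------------------------------------------
    log("[evaluate] scoring the held-out test partition")
    te = hist.test_idx if len(hist.test_idx) else hist.val_idx
    pred = predict(model, X[te])
    report = evaluate(pred, y[te], sd_as_printed=bool(cfg.eval.get("sd_as_printed", False)))
    report_path = out / "report.json"
    report.write_json(report_path)
    register("report", report_path, depends_on=["checkpoint", "processed"])
    pred_path = out / "predictions.csv"
    write_predictions_csv(pred_path, pred, y[te], record_ids=rid[te], segment_index=te)
    register("predictions", pred_path, depends_on=["checkpoint", "processed"])
    if cfg.eval.get("plots", False):
        for p in save_plots(pred, y[te], out / "plots"):
            register(Path(p).stem, Path(p), depends_on=["predictions"])

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    log(f"[done] artifacts in {out}")
    return manifest


def fixture_suite(out_dir) -> dict:
    """Write the canonical plain-text fixtures and a hash manifest."""
    from .fixtures import (
        clean_record_30s, make_quality_batch, se_toy_example, error_vector_example,
    )

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    rec = clean_record_30s()
    p = out / "clean_record_30s.csv"
    write_record_csv(rec, p)
    written.append(p)

    for i, seg in enumerate(make_quality_batch()):
        p = out / f"quality_segment_{i}.csv"
        with open(p, "w") as fh:
            fh.write(f"# sbp_ref={seg.sbp_ref} dbp_ref={seg.dbp_ref}\n")
            fh.write("ppg,abp\n")
            for a, b in zip(seg.ppg_window, seg.abp_window):
                fh.write(f"{a:.8g},{b:.8g}\n")
        written.append(p)

    p = out / "se_toy_example.json"
    p.write_text(json.dumps(se_toy_example(), indent=2))
    written.append(p)

    p = out / "error_vector_example.json"
    p.write_text(json.dumps(error_vector_example(), indent=2))
    written.append(p)

    manifest = {q.name: _sha256(q) for q in written}
    (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=2))
    return manifest
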