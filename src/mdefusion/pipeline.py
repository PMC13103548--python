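"""Stage orchestration: simulate -> preprocess -> features -> train -> evaluate.

Each stage reads its inputs from the previous stage's output directory,
writes its products plus a ``manifest.json`` naming its inputs, seeds and
the package version, and can be re-run independently. All randomness
derives from the root seed (stage-specific offsets keep streams disjoint).
"""
from __future__ import annotations

import csv
import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import __version__
from .config import PipelineConfig
from .edf import read_edf
from .evaluate import (compute_metrics, confusion_counts, percent,
                       subject_level_eval)
from .features import fit_ica, ica_spatial, wavelet_time_frequency
from .hcsae import HCSAEConfig
from .balstm import BALSTMConfig
from .model import (MDEFusion, ModelConfig, condense_time, count_params_flops,
                    load_checkpoint, save_checkpoint, train)
from .montage import load_montage_table
from .preprocess import (bandlimit, harmonize_channels, normalize,
                         segment_windows, shuffle_segments, split_subjects,
                         undersample_subjects)
from .synthetic import (PRESETS, ClassEffect, SyntheticSpec, generate_cohort,
                        write_fixture_edf)
from .types import LABEL_TO_INDEX, MDEFusionError, ParameterError

PARTITIONS = ("train", "val", "test")


class DependencyError(MDEFusionError):
    """A stage's upstream output is missing."""


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(cfg.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_manifest(stage_dir: Path, stage: str, cfg: PipelineConfig,
                    inputs: List[str], outputs: List[str], seed: int) -> None:
    stage_dir.mkdir(parents=True, exist_ok=True)
    (stage_dir / "manifest.json").write_text(json.dumps({
        "stage": stage,
        "package_version": __version__,
        "config_hash": _config_hash(cfg),
        "seed": seed,
        "inputs": inputs,
        "outputs": outputs,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }, indent=1))


def _require(path: Path, what: str) -> Path:
    if not path.exists():
        raise DependencyError(f"missing upstream output: {what} ({path})")
    return path


# ---------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig, out_dir: Path) -> Path:
    sim = cfg.simulate
    if sim.preset is not None:
        base = PRESETS[sim.preset]
        spec = SyntheticSpec(
            n_subjects_per_group=sim.n_subjects_per_group
            if "n_subjects_per_group" in sim.model_fields_set
            else base.n_subjects_per_group,
            duration_s=sim.duration_s if "duration_s" in sim.model_fields_set
            else base.duration_s,
            fs=sim.fs if "fs" in sim.model_fields_set else base.fs,
            montage_name=sim.montage_name if "montage_name" in sim.model_fields_set
            else base.montage_name,
            class_effect=ClassEffect(band=sim.band, power_ratio=sim.power_ratio,
                                     corr_shift=sim.corr_shift),
            noise_sd=sim.noise_sd, seed=cfg.seed)
    else:
        spec = SyntheticSpec(
            n_subjects_per_group=sim.n_subjects_per_group,
            duration_s=sim.duration_s, fs=sim.fs, montage_name=sim.montage_name,
            class_effect=ClassEffect(band=sim.band, power_ratio=sim.power_ratio,
                                     corr_shift=sim.corr_shift),
            noise_sd=sim.noise_sd, seed=cfg.seed)
    stage_dir = out_dir / "simulate"
    stage_dir.mkdir(parents=True, exist_ok=True)
    recs = generate_cohort(spec)
    paths = write_fixture_edf(recs, stage_dir)
    _write_manifest(stage_dir, "simulate", cfg, inputs=[],
                    outputs=[p.name for p in paths], seed=cfg.seed)
    return stage_dir


def stage_preprocess(cfg: PipelineConfig, out_dir: Path,
                     in_dir: Optional[Path] = None) -> Path:
    pp = cfg.preprocess
    in_dir = _require(Path(in_dir) if in_dir else out_dir / "simulate",
                      "EDF directory (simulate stage)")
    edf_paths = sorted(in_dir.glob("*.edf"))
    if not edf_paths:
        raise DependencyError(f"no EDF files in {in_dir}")
    stage_dir = out_dir / "preprocess"
    stage_dir.mkdir(parents=True, exist_ok=True)

    montage = load_montage_table()
    recs = []
    for p in edf_paths:
        rec = read_edf(p)
        high = min(pp.high, 0.45 * rec.fs)   # keep the edge below Nyquist
        rec = bandlimit(rec, pp.low, high)
        rec = normalize(rec)
        if pp.harmonize:
            rec = harmonize_channels(rec, montage)
        recs.append(rec)

    if pp.undersample_to is not None:
        recs = undersample_subjects(recs, pp.undersample_to, seed=cfg.seed + 11)
    rem = 1.0 - pp.train_frac
    plan = split_subjects(recs, fractions=(pp.train_frac, rem / 2, rem / 2),
                          seed=cfg.seed + 12)

    manifest_rows = []
    outputs = []
    for part in PARTITIONS:
        subjects = set(plan.subjects(part))
        segs = []
        for rec in recs:
            if rec.subject_id in subjects:
                segs.extend(segment_windows(rec, pp.win_s, pp.stride_s))
        segs = shuffle_segments(segs, seed=cfg.seed + 13)
        windows = np.stack([s.window for s in segs]).astype(np.float32)
        np.save(stage_dir / f"{part}_windows.npy", windows)
        outputs.append(f"{part}_windows.npy")
        for i, s in enumerate(segs):
            manifest_rows.append({"partition": part, "index": i,
                                  "subject_id": s.subject_id, "label": s.label,
                                  "t0": s.t0, "fs": s.fs})
    with open(stage_dir / "segments.csv", "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=["partition", "index", "subject_id",
                                           "label", "t0", "fs"])
        w.writeheader()
        w.writerows(manifest_rows)
    _write_manifest(stage_dir, "preprocess", cfg,
                    inputs=[p.name for p in edf_paths],
                    outputs=outputs + ["segments.csv"], seed=cfg.seed)
    return stage_dir


def _load_segments(pre_dir: Path) -> Tuple[Dict[str, np.ndarray], Dict[str, list]]:
    windows = {}
    meta: Dict[str, list] = {p: [] for p in PARTITIONS}
    with open(pre_dir / "segments.csv") as fh:
        for row in csv.DictReader(fh):
            meta[row["partition"]].append(row)
    for part in PARTITIONS:
        windows[part] = np.load(pre_dir / f"{part}_windows.npy")
    return windows, meta


def stage_features(cfg: PipelineConfig, out_dir: Path,
                   in_dir: Optional[Path] = None) -> Path:
    ft = cfg.features
    pre_dir = _require(Path(in_dir) if in_dir else out_dir / "preprocess",
                       "segment directory (preprocess stage)")
    _require(pre_dir / "segments.csv", "segment manifest")
    stage_dir = out_dir / "features"
    stage_dir.mkdir(parents=True, exist_ok=True)
    windows, meta = _load_segments(pre_dir)

    seq_len = cfg.train.seq_len
    ica = fit_ica(list(windows["train"].astype(np.float64)),
                  n_components=ft.n_components, seed=cfg.seed + 21,
                  max_samples=ft.ica_max_samples)

    def extract(part: str) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        X = windows[part].astype(np.float64)
        x1_list, x2_list = [], []
        for w in X:
            F1 = wavelet_time_frequency(w, mode=ft.mode, wavelet=ft.wavelet,
                                        depth_or_scales=ft.depth)
            F1 = F1.reshape(-1, F1.shape[-1])
            x1_list.append(condense_time(F1, seq_len))
            x2_list.append(condense_time(ica_spatial(w, ica), seq_len))
        y = np.array([LABEL_TO_INDEX[r["label"]] for r in meta[part]], dtype=np.int64)
        return (np.stack(x1_list).astype(np.float32),
                np.stack(x2_list).astype(np.float32), y)

    data = {part: extract(part) for part in PARTITIONS}
    # z-score per feature channel with training-partition statistics
    stats = {}
    for name, xi in (("x1", 0), ("x2", 1)):
        tr = data["train"][xi]
        mean = tr.mean(axis=(0, 2), keepdims=True)
        sd = np.maximum(tr.std(axis=(0, 2), keepdims=True), 1e-6)
        stats[name] = (mean, sd)
    outputs = []
    for part in PARTITIONS:
        x1, x2, y = data[part]
        x1 = (x1 - stats["x1"][0]) / stats["x1"][1]
        x2 = (x2 - stats["x2"][0]) / stats["x2"][1]
        np.savez(stage_dir / f"{part}.npz", x1=x1, x2=x2, y=y)
        outputs.append(f"{part}.npz")
    (stage_dir / "meta.json").write_text(json.dumps({
        "mode": ft.mode, "wavelet": ft.wavelet, "depth": ft.depth,
        "seq_len": seq_len, "d_f1": int(data["train"][0].shape[1]),
        "d_f2": int(data["train"][1].shape[1]),
        "ica_seed": cfg.seed + 21,
    }, indent=1))
    _write_manifest(stage_dir, "features", cfg,
                    inputs=["segments.csv"] + [f"{p}_windows.npy" for p in PARTITIONS],
                    outputs=outputs + ["meta.json"], seed=cfg.seed)
    return stage_dir


def _model_config(cfg: PipelineConfig, d_f1: int, d_f2: int) -> ModelConfig:
    return ModelConfig(
        hcsae=HCSAEConfig(abstract_channels=cfg.hcsae.abstract_channels,
                          n_1x3_layers=cfg.hcsae.n_1x3_layers,
                          dropout_q=cfg.hcsae.dropout_q,
                          latent_channels=cfg.hcsae.latent_channels,
                          recon_weight=cfg.hcsae.recon_weight,
                          seed=cfg.seed + 31),
        balstm=BALSTMConfig(hidden=cfg.balstm.hidden, layers=cfg.balstm.layers,
                            input_dim=cfg.hcsae.latent_channels,
                            seed=cfg.seed + 32),
        d_f1=d_f1, d_f2=d_f2, seq_len=cfg.train.seq_len,
        lr=cfg.train.lr, batch=cfg.train.batch, epochs=cfg.train.epochs,
        decay=cfg.train.decay, decay_every=cfg.train.decay_every,
        seed=cfg.seed + 30)


def stage_train(cfg: PipelineConfig, out_dir: Path,
                features_dir: Optional[Path] = None) -> Path:
    feat_dir = _require(Path(features_dir) if features_dir else out_dir / "features",
                        "feature directory (features stage)")
    meta = json.loads(_require(feat_dir / "meta.json", "feature meta").read_text())
    stage_dir = out_dir / "train"
    stage_dir.mkdir(parents=True, exist_ok=True)

    def load(part):
        with np.load(feat_dir / f"{part}.npz") as z:
            return z["x1"], z["x2"], z["y"]

    mcfg = _model_config(cfg, meta["d_f1"], meta["d_f2"])
    model = MDEFusion(mcfg)
    model, history = train(model, load("train"), load("val"), cfg=mcfg)
    ckpt = save_checkpoint(model, stage_dir / "checkpoint.npz")
    with open(stage_dir / "history.csv", "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=list(history.epochs[0].keys()))
        w.writeheader()
        w.writerows(history.epochs)
    report = count_params_flops(model)
    (stage_dir / "complexity.json").write_text(json.dumps(
        {"params": report.params, "flops": report.flops}, indent=1))
    _write_manifest(stage_dir, "train", cfg,
                    inputs=[f"{p}.npz" for p in PARTITIONS],
                    outputs=[ckpt.name, "history.csv", "complexity.json"],
                    seed=cfg.seed)
    return stage_dir


def stage_evaluate(cfg: PipelineConfig, out_dir: Path,
                   run_dir: Optional[Path] = None,
                   features_dir: Optional[Path] = None) -> Path:
    feat_dir = _require(Path(features_dir) if features_dir else out_dir / "features",
                        "feature directory (features stage)")
    train_dir = _require(Path(run_dir) if run_dir else out_dir / "train",
                         "trained run (train stage)")
    ckpt = _require(train_dir / "checkpoint.npz", "model checkpoint")
    pre_dir = _require(out_dir / "preprocess", "segment manifest directory")
    stage_dir = out_dir / "evaluate"
    stage_dir.mkdir(parents=True, exist_ok=True)

    model = load_checkpoint(ckpt)
    _, meta = _load_segments(pre_dir)
    report = {}
    index_to_label = {v: k for k, v in LABEL_TO_INDEX.items()}
    for part in ("val", "test"):
        with np.load(feat_dir / f"{part}.npz") as z:
            x1, x2, y = z["x1"], z["x2"], z["y"]
        probs = model.predict_proba(x1, x2)
        pred = probs.argmax(axis=1)
        y_true = [index_to_label[int(v)] for v in y]
        y_pred = [index_to_label[int(v)] for v in pred]
        seg_counts = confusion_counts(y_true, y_pred)
        seg_metrics = compute_metrics(seg_counts)
        subj_results = [(meta[part][i]["subject_id"], y_true[i], y_pred[i])
                        for i in range(len(y_true))]
        outcomes, subj_counts, subj_acc = subject_level_eval(
            subj_results, threshold=cfg.evaluate.subject_threshold)
        report[part] = {
            "segment": {"counts": {
                "tp": seg_counts.tp, "fp": seg_counts.fp,
                "fn": seg_counts.fn, "tn": seg_counts.tn},
                "metrics_percent": seg_metrics.as_percent()},
            "subject": {"counts": {
                "tp": subj_counts.tp, "fp": subj_counts.fp,
                "fn": subj_counts.fn, "tn": subj_counts.tn},
                "accuracy_percent": percent(subj_acc, 2),
                "n_subjects": len(outcomes)},
        }
        with open(stage_dir / f"confusion_{part}.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["level", "tp", "fp", "fn", "tn"])
            w.writerow(["segment", seg_counts.tp, seg_counts.fp,
                        seg_counts.fn, seg_counts.tn])
            w.writerow(["subject", subj_counts.tp, subj_counts.fp,
                        subj_counts.fn, subj_counts.tn])
    (stage_dir / "report.json").write_text(json.dumps(report, indent=1))
    _write_manifest(stage_dir, "evaluate", cfg,
                    inputs=["checkpoint.npz", "val.npz", "test.npz"],
                    outputs=["report.json", "confusion_val.csv",
                             "confusion_test.csv"], seed=cfg.seed)
    return stage_dir


STAGES = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "features": stage_features,
    "train": stage_train,
    "evaluate": stage_evaluate,
}


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    stages: Dict[str, str]


def run_pipeline(cfg: PipelineConfig,
                 stages: Optional[Sequence[str]] = None) -> RunManifest:
    """Execute the requested stages in canonical order."""
    stages = list(stages) if stages else list(STAGES)
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ParameterError(f"unknown stage(s): {unknown}")
    out_dir = Path(cfg.out_dir)
    done: Dict[str, str] = {}
    for name in STAGES:       # canonical order regardless of input order
        if name in stages:
            done[name] = str(STAGES[name](cfg, out_dir))
    manifest = RunManifest(config_hash=_config_hash(cfg), seed=cfg.seed,
                           version=__version__, stages=done)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "run_manifest.json").write_text(json.dumps(vars(manifest), indent=1))
    return manifest
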