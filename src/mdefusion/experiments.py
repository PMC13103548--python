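"""Self-contained end-to-end experiments on synthetic cohorts.

These run the whole methodological chain in memory — cohort generation,
band-limiting, normalization, montage harmonization, subject-independent
splitting, windowing, wavelet + ICA feature extraction, HCSAE + BALSTM
training, and subject-level scoring — without touching disk. They are the
package's own recoverability checks: with a strong injected class effect
the pipeline should recognize held-out subjects nearly perfectly.

The ``fast`` model profile used here (narrower layers, sequence length 8,
batch 128, 50 epochs) keeps a full experiment in CPU minutes; the cohort
conditions themselves (subjects, duration, sampling rate, effect size) are
the quantities under study and are not reduced.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .balstm import BALSTMConfig
from .hcsae import HCSAEConfig
from .features import fit_ica, ica_spatial, wavelet_time_frequency
from .model import MDEFusion, ModelConfig, condense_time, train
from .preprocess import (bandlimit, harmonize_channels, normalize,
                         segment_windows, shuffle_segments, split_subjects)
from .synthetic import ClassEffect, SyntheticSpec, generate_cohort
from .types import LABEL_TO_INDEX, Recording, Segment
from .evaluate import subject_level_eval

#: reduced-width model profile for CPU-scale experiments
FAST_PROFILE = dict(abstract_channels=16, n_1x3_layers=1, latent_channels=32,
                    hidden=32, seq_len=8, batch=128, epochs=50)


@dataclass
class ExperimentResult:
    subject_accuracy: float
    segment_accuracy: float
    n_subjects_heldout: int
    n_segments_heldout: int
    history_final_loss: float


def _prepare_features(recs: List[Recording], seed: int, win_s: float = 2.0,
                      stride_s: float = 1.0, depth: int = 3,
                      seq_len: int = 8, wavelet: str = "db4"
                      ) -> Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray, list]]:
    """Preprocess + split + extract condensed (x1, x2, y, subject_ids)."""
    processed = []
    for rec in recs:
        high = min(100.0, 0.45 * rec.fs)
        rec = normalize(bandlimit(rec, 0.0, high))
        processed.append(harmonize_channels(rec))
    plan = split_subjects(processed, seed=seed + 1)
    parts: Dict[str, List[Segment]] = {"train": [], "val": [], "test": []}
    for rec in processed:
        parts[plan.assignment[rec.subject_id]].extend(
            segment_windows(rec, win_s, stride_s))
    for p in parts:
        parts[p] = shuffle_segments(parts[p], seed=seed + 2)

    ica = fit_ica([s.window for s in parts["train"]], seed=seed + 3)

    def extract(segs: List[Segment]):
        x1, x2, y, sids = [], [], [], []
        for s in segs:
            F1 = wavelet_time_frequency(s.window, "wpt", wavelet, depth)
            x1.append(condense_time(F1.reshape(-1, F1.shape[-1]), seq_len))
            x2.append(condense_time(ica_spatial(s.window, ica), seq_len))
            y.append(LABEL_TO_INDEX[s.label])
            sids.append(s.subject_id)
        return (np.stack(x1).astype(np.float32), np.stack(x2).astype(np.float32),
                np.asarray(y, dtype=np.int64), sids)

    data = {p: extract(parts[p]) for p in parts}
    # train-partition z-scoring per feature channel
    for xi in (0, 1):
        tr = data["train"][xi]
        mean = tr.mean(axis=(0, 2), keepdims=True)
        sd = np.maximum(tr.std(axis=(0, 2), keepdims=True), 1e-6)
        for p in data:
            x = (data[p][xi] - mean) / sd
            data[p] = data[p][:xi] + (x.astype(np.float32),) + data[p][xi + 1:]
    return data


def subject_recovery_experiment(seed: int, n_subjects_per_group: int = 20,
                                duration_s: float = 60.0, fs: float = 128.0,
                                montage_name: str = "std16",
                                power_ratio: float = 3.0, band: str = "alpha",
                                corr_shift: float = 0.2, noise_sd: float = 1.0,
                                epochs: Optional[int] = None,
                                profile: Optional[dict] = None
                                ) -> ExperimentResult:
    """Train on a synthetic cohort and score all held-out subjects
    (validation + test partitions) with the >95% subject rule."""
    profile = dict(FAST_PROFILE, **(profile or {}))
    spec = SyntheticSpec(
        n_subjects_per_group=n_subjects_per_group, duration_s=duration_s,
        fs=fs, montage_name=montage_name,
        class_effect=ClassEffect(band=band, power_ratio=power_ratio,
                                 corr_shift=corr_shift),
        noise_sd=noise_sd, seed=seed)
    recs = generate_cohort(spec)
    data = _prepare_features(recs, seed=seed + 10, depth=3,
                             seq_len=profile["seq_len"])

    mcfg = ModelConfig(
        hcsae=HCSAEConfig(abstract_channels=profile["abstract_channels"],
                          n_1x3_layers=profile["n_1x3_layers"],
                          latent_channels=profile["latent_channels"],
                          dropout_q=0.3, recon_weight=0.1, seed=seed + 20),
        balstm=BALSTMConfig(hidden=profile["hidden"], layers=3,
                            input_dim=profile["latent_channels"], seed=seed + 21),
        d_f1=data["train"][0].shape[1], d_f2=data["train"][1].shape[1],
        seq_len=profile["seq_len"], batch=profile["batch"],
        epochs=epochs if epochs is not None else profile["epochs"],
        seed=seed + 22)
    model = MDEFusion(mcfg)
    x1, x2, y, _ = data["train"]
    vx1, vx2, vy, _ = data["val"]
    model, history = train(model, (x1, x2, y), (vx1, vx2, vy), cfg=mcfg)

    # held-out = validation + test subjects (none saw training)
    results = []
    n_seg = 0
    correct_seg = 0
    for part in ("val", "test"):
        px1, px2, py, sids = data[part]
        pred = model.predict_proba(px1, px2).argmax(axis=1)
        correct_seg += int((pred == py).sum())
        n_seg += len(py)
        inv = {v: k for k, v in LABEL_TO_INDEX.items()}
        results.extend((sids[i], inv[int(py[i])], inv[int(pred[i])])
                       for i in range(len(py)))
    outcomes, _, subj_acc = subject_level_eval(results)
    return ExperimentResult(
        subject_accuracy=subj_acc,
        segment_accuracy=correct_seg / n_seg,
        n_subjects_heldout=len(outcomes),
        n_segments_heldout=n_seg,
        history_final_loss=history.epochs[-1]["loss"])
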