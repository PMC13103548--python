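"""Synthetic two-class EEG cohorts.

Each channel is a sum of one random-phase sinusoid per canonical rhythm
band (delta through gamma), with amplitude proportional to 1/f at the band
centre (the characteristic 1/f spectral tilt of scalp EEG), plus white
Gaussian noise. The patient group ("SZ") differs from controls ("HC") in
two controllable ways:

* the amplitude of one chosen band is scaled by ``sqrt(power_ratio)`` so
  its Welch band power is scaled by ``power_ratio``;
* a shared latent oscillation is mixed into all channels with weight
  ``corr_shift``, raising inter-channel correlation and giving spatial
  unmixing a recoverable structure.

This emulates the band-power and connectivity differences that EEG
classifiers exploit; it does not attempt biophysical forward modelling or
artifact (blink/EMG) simulation.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np

from . import edf
from .montage import montage_channels
from .types import ConfigurationError, ParameterError, Recording

#: canonical EEG rhythm bands, Hz
BANDS: Dict[str, Tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 45.0),
}

#: overall oscillation amplitude scale (microvolts x Hz); per band the
#: sinusoid amplitude is AMP_SCALE / f_center
AMP_SCALE = 10.0


@dataclass(frozen=True)
class ClassEffect:
    """How the SZ group differs from HC."""

    band: str = "alpha"
    power_ratio: float = 3.0
    corr_shift: float = 0.2

    def validate(self) -> None:
        if self.band not in BANDS:
            raise ConfigurationError(f"unknown band {self.band!r}; choose from {sorted(BANDS)}")
        if self.power_ratio <= 0:
            raise ParameterError("power_ratio must be > 0")
        if not -1.0 <= self.corr_shift <= 1.0:
            raise ParameterError("corr_shift must be in [-1, 1]")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic cohort."""

    n_subjects_per_group: int = 10
    duration_s: float = 60.0
    fs: float = 128.0
    montage_name: str = "std16"
    class_effect: ClassEffect = field(default_factory=ClassEffect)
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects_per_group < 1:
            raise ParameterError("n_subjects_per_group must be >= 1")
        n = self.duration_s * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ParameterError("duration_s x fs must be an integer sample count")
        montage_channels(self.montage_name)  # raises ConfigurationError if unknown
        self.class_effect.validate()


# presets mirroring the two public-cohort geometries (19 ch / 15 min and
# 16 ch / 1 min); sampling rates are configurable module defaults
PRESETS: Dict[str, SyntheticSpec] = {
    "repod-like": SyntheticSpec(n_subjects_per_group=14, duration_s=900.0, fs=250.0,
                                montage_name="std19"),
    "nnci-like": SyntheticSpec(n_subjects_per_group=39, duration_s=60.0, fs=128.0,
                               montage_name="std16"),
}


def _subject_signal(rng: np.random.Generator, channels: List[str], n: int,
                    fs: float, spec: SyntheticSpec, is_sz: bool) -> np.ndarray:
    t = np.arange(n) / fs
    n_ch = len(channels)
    sig = np.zeros((n_ch, n))
    eff = spec.class_effect
    for band, (lo, hi) in BANDS.items():
        if hi >= fs / 2:  # band not representable at this sampling rate
            continue
        f_center = 0.5 * (lo + hi)
        amp = AMP_SCALE / f_center
        if is_sz and band == eff.band:
            amp *= np.sqrt(eff.power_ratio)
        freqs = rng.uniform(lo, hi, size=n_ch)
        phases = rng.uniform(0, 2 * np.pi, size=n_ch)
        sig += amp * np.sin(2 * np.pi * freqs[:, None] * t[None, :] + phases[:, None])
    if is_sz and eff.corr_shift != 0.0:
        # shared latent oscillation mixed into every channel
        lo, hi = BANDS[eff.band]
        f = rng.uniform(lo, hi)
        ph = rng.uniform(0, 2 * np.pi)
        shared = (AMP_SCALE / (0.5 * (lo + hi))) * np.sin(2 * np.pi * f * t + ph)
        sig += eff.corr_shift * shared[None, :]
    sig += rng.normal(0.0, spec.noise_sd, size=(n_ch, n))
    return sig


def generate_cohort(spec: SyntheticSpec) -> List[Recording]:
    """Generate ``2 x n_subjects_per_group`` recordings, fully seeded.

    Subjects are named ``SZ01..`` / ``HC01..``; every subject draws from an
    independent child stream of the cohort seed, so cohorts are bitwise
    reproducible and subjects are order-independent.
    """
    spec.validate()
    channels = montage_channels(spec.montage_name)
    n = int(round(spec.duration_s * spec.fs))
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(2 * spec.n_subjects_per_group)
    recs: List[Recording] = []
    idx = 0
    for group in ("SZ", "HC"):
        for k in range(spec.n_subjects_per_group):
            rng = np.random.default_rng(children[idx])
            idx += 1
            sig = _subject_signal(rng, channels, n, spec.fs, spec, group == "SZ")
            recs.append(Recording(
                subject_id=f"{group}{k + 1:02d}",
                group=group,
                fs=spec.fs,
                channels=list(channels),
                signal=sig,
                dataset_tag=f"synthetic-{spec.montage_name}",
            ))
    return recs


def write_fixture_edf(recs: List[Recording], out_dir) -> List[Path]:
    """Write one EDF (plus JSON sidecar) per recording; returns the EDF paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for rec in recs:
        p = out_dir / f"{rec.subject_id}.edf"
        edf.write_edf(rec, p)
        edf.write_sidecar(rec, p)
        paths.append(p)
    return paths
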