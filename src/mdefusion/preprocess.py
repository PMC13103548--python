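"""EDF preprocessing: band-limiting, normalization, montage harmonization,
windowing and subject-independent partitioning.

The harmonization target is the unified 19-channel 10-20 set: recordings
that already carry 19 channels are reordered; 16-channel recordings get
the three midline sites (FCz, CPz, Oz) estimated by spherical spline
interpolation (Perrin-style, order m=4) from the measured electrodes.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy.signal import butter, sosfiltfilt
from scipy.special import eval_legendre

from .montage import CHANNELS_19, EXTRA_19, MontageSpec, load_montage_table
from .types import (ConfigurationError, DegenerateInputError, ParameterError,
                    Recording, Segment)

# re-export: reading EDF lives in the io layer
from .edf import read_edf as read_recording  # noqa: F401


def bandlimit(rec: Recording, low: float, high: float, order: int = 8) -> Recording:
    """Zero-phase Butterworth band-limit to (low, high) Hz.

    ``low = 0`` degenerates to a pure low-pass (a 0-Hz high-pass edge is
    vacuous). Filtering is forward-backward (no phase distortion); the
    order-8 default gives a steep enough skirt that a tone 20% above the
    edge is suppressed below a few percent RMS.
    """
    nyq = rec.fs / 2.0
    if not (0 <= low < high):
        raise ParameterError("need 0 <= low < high")
    if high >= nyq:
        raise ParameterError(f"high={high} must be < Nyquist ({nyq})")
    if low <= 0:
        sos = butter(order, high, btype="lowpass", fs=rec.fs, output="sos")
    else:
        sos = butter(order, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    filtered = sosfiltfilt(sos, rec.signal, axis=1)
    return rec.copy_with(signal=filtered)


def normalize(rec: Recording) -> Recording:
    """Per-channel z-score (mean 0, SD 1) over the whole recording."""
    mean = rec.signal.mean(axis=1, keepdims=True)
    sd = rec.signal.std(axis=1, keepdims=True)
    flat = np.nonzero(sd.ravel() == 0)[0]
    if flat.size:
        names = [rec.channels[i] for i in flat]
        raise DegenerateInputError(f"constant channel(s), cannot normalize: {names}")
    return rec.copy_with(signal=(rec.signal - mean) / sd)


# ---------------------------------------------------------------------------
# spherical spline interpolation (Perrin et al. style)

def _g_matrix(cosang: np.ndarray, m: int = 4, n_terms: int = 20) -> np.ndarray:
    """g(cos theta) = 1/(4 pi) * sum_n (2n+1)/(n (n+1))^m * P_n(cos theta)."""
    g = np.zeros_like(cosang, dtype=float)
    for n in range(1, n_terms + 1):
        g += (2 * n + 1) / (n * (n + 1)) ** m * eval_legendre(n, cosang)
    return g / (4 * np.pi)


def spherical_spline_interpolate(rec: Recording, montage: MontageSpec,
                                 targets: Sequence[str], m: int = 4,
                                 n_terms: int = 20, ridge: float = 1e-5,
                                 reorder: bool = True) -> Recording:
    """Estimate channels at ``targets`` by spherical spline interpolation.

    Original channels pass through unchanged; the estimated channels are
    appended (or, when the result is exactly the unified 19-channel set
    and ``reorder`` is true, the output is put in canonical order). The
    small ridge term on the spline system keeps it well-conditioned.
    """
    if rec.n_channels < 4:
        raise ParameterError("need at least 4 measured channels for spline interpolation")
    src = montage.coords(rec.channels)         # may raise ConfigurationError
    try:
        dst = montage.coords(targets)
    except ConfigurationError as exc:
        raise ConfigurationError(f"target with unknown coordinates: {exc}") from exc

    n_src = src.shape[0]
    G = _g_matrix(np.clip(src @ src.T, -1.0, 1.0), m, n_terms)
    A = np.zeros((n_src + 1, n_src + 1))
    A[:n_src, :n_src] = G + ridge * np.eye(n_src)
    A[:n_src, n_src] = 1.0
    A[n_src, :n_src] = 1.0
    rhs = np.zeros((n_src + 1, rec.n_samples))
    rhs[:n_src] = rec.signal
    sol = np.linalg.solve(A, rhs)
    c, c0 = sol[:n_src], sol[n_src]

    Gt = _g_matrix(np.clip(dst @ src.T, -1.0, 1.0), m, n_terms)
    est = Gt @ c + c0[None, :]

    channels = list(rec.channels) + list(targets)
    signal = np.vstack([rec.signal, est])
    if reorder and sorted(channels) == sorted(CHANNELS_19):
        order = [channels.index(ch) for ch in CHANNELS_19]
        channels = list(CHANNELS_19)
        signal = signal[order]
    return rec.copy_with(channels=channels, signal=signal)


def harmonize_channels(rec: Recording, montage: MontageSpec | None = None,
                       targets: Sequence[str] = tuple(EXTRA_19)) -> Recording:
    """Bring a recording onto the unified 19-channel set in canonical order."""
    if montage is None:
        montage = load_montage_table()
    have = set(rec.channels)
    missing = [t for t in CHANNELS_19 if t not in have]
    if missing:
        unexpected = [t for t in missing if t not in targets]
        if unexpected:
            raise ConfigurationError(
                f"cannot harmonize: missing channels {unexpected} are not "
                f"interpolation targets {list(targets)}")
        rec = spherical_spline_interpolate(rec, montage, missing)
    if rec.channels != CHANNELS_19:
        order = [rec.channels.index(ch) for ch in CHANNELS_19]
        rec = rec.copy_with(channels=list(CHANNELS_19), signal=rec.signal[order])
    return rec


# ---------------------------------------------------------------------------
# windowing and partitioning

def segment_windows(rec: Recording, win_s: float = 2.0,
                    stride_s: float = 1.0) -> List[Segment]:
    """Slice a recording into fixed windows (count = floor((T-w)/s) + 1)."""
    if win_s <= 0 or stride_s <= 0:
        raise ParameterError("win_s and stride_s must be positive")
    if win_s > rec.duration_s + 1e-12:
        warnings.warn(f"window {win_s}s exceeds recording duration "
                      f"{rec.duration_s}s; returning no segments")
        return []
    win = int(round(win_s * rec.fs))
    stride = int(round(stride_s * rec.fs))
    segments = []
    for start in range(0, rec.n_samples - win + 1, stride):
        segments.append(Segment(
            subject_id=rec.subject_id,
            label=rec.group,
            window=rec.signal[:, start:start + win].copy(),
            t0=start / rec.fs,
            fs=rec.fs,
        ))
    return segments


@dataclass(frozen=True)
class SplitPlan:
    """subject_id -> partition map, subject-disjoint by construction."""

    assignment: Dict[str, str]
    seed: int

    def subjects(self, partition: str) -> List[str]:
        return sorted(s for s, p in self.assignment.items() if p == partition)

    def __post_init__(self) -> None:
        parts = set(self.assignment.values())
        if not parts <= {"train", "val", "test"}:
            raise ParameterError(f"unknown partition names: {parts}")


def split_subjects(recs: Sequence[Recording],
                   fractions: Tuple[float, float, float] = (0.8, 0.1, 0.1),
                   seed: int = 0) -> SplitPlan:
    """Subject-independent split: per class, floor(train_frac x n) subjects
    train; the remainder goes half to validation and half to test, an odd
    leftover alternating between validation (first class) and test (next).

    That alternation is what makes the canonical cohort sizes come out as
    14+14 -> 22/3/3 and 39+39 -> 62/8/8.
    """
    train_frac = fractions[0]
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ParameterError("fractions must sum to 1")
    by_class: Dict[str, List[str]] = {}
    for r in recs:
        by_class.setdefault(r.group, []).append(r.subject_id)
    rng = np.random.default_rng(seed)
    assignment: Dict[str, str] = {}
    leftover_to_val = True
    for group in sorted(by_class):
        subjects = sorted(set(by_class[group]))
        n = len(subjects)
        n_train = int(np.floor(train_frac * n))
        rem = n - n_train
        if n < 3 or rem < 1:
            raise ParameterError(
                f"class {group}: {n} subjects are too few for a 3-way split")
        perm = rng.permutation(n)
        shuffled = [subjects[i] for i in perm]
        n_val = rem // 2
        n_test = rem // 2
        if rem % 2:
            if leftover_to_val:
                n_val += 1
            else:
                n_test += 1
            leftover_to_val = not leftover_to_val
        for s in shuffled[:n_train]:
            assignment[s] = "train"
        for s in shuffled[n_train:n_train + n_val]:
            assignment[s] = "val"
        for s in shuffled[n_train + n_val:n_train + n_val + n_test]:
            assignment[s] = "test"
    plan = SplitPlan(assignment=assignment, seed=seed)
    # invariant: partitions are subject-disjoint by construction of the dict;
    # verify each partition is non-empty
    for p in ("train", "val", "test"):
        if not plan.subjects(p):
            raise ParameterError(f"partition {p!r} is empty")
    return plan


def undersample_subjects(recs: Sequence[Recording], target_per_class: int,
                         seed: int = 0) -> List[Recording]:
    """Randomly drop whole subjects from larger classes until balanced."""
    by_class: Dict[str, List[Recording]] = {}
    for r in recs:
        by_class.setdefault(r.group, []).append(r)
    for group, group_recs in by_class.items():
        if target_per_class > len(group_recs):
            raise ParameterError(
                f"target {target_per_class} exceeds class {group} size {len(group_recs)}")
    rng = np.random.default_rng(seed)
    kept: List[Recording] = []
    for group in sorted(by_class):
        group_recs = sorted(by_class[group], key=lambda r: r.subject_id)
        idx = rng.permutation(len(group_recs))[:target_per_class]
        kept.extend(group_recs[i] for i in sorted(idx))
    return kept


def shuffle_segments(segments: List[Segment], seed: int) -> List[Segment]:
    """Seeded in-partition shuffle (removes temporal ordering)."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(segments))
    return [segments[i] for i in order]
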