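"""Core containers shared across the pipeline.

Labels use ``"SZ"`` (schizophrenia, the positive class) and ``"HC"``
(healthy control) throughout.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Literal

import numpy as np

Label = Literal["SZ", "HC"]
LABELS: tuple = ("SZ", "HC")

#: integer codes used by the classifier head (SZ = positive class = 1)
LABEL_TO_INDEX: Dict[str, int] = {"HC": 0, "SZ": 1}


class MDEFusionError(Exception):
    """Base class for package errors."""


class ConfigurationError(MDEFusionError):
    """Invalid configuration (unknown montage, bad hyperparameter...)."""


class ParameterError(MDEFusionError):
    """Operation called with out-of-domain parameters."""


class DegenerateInputError(MDEFusionError):
    """Input is structurally valid but degenerate (constant channel...)."""


class FormatError(MDEFusionError):
    """A file or record does not match the expected format."""


class DivergenceError(MDEFusionError):
    """Training produced a non-finite loss."""


@dataclass
class Recording:
    """One subject's multichannel EEG signal.

    ``signal`` is channels x samples, in microvolts unless a previous
    stage (normalize) rescaled it.
    """

    subject_id: str
    group: str
    fs: float
    channels: List[str]
    signal: np.ndarray
    dataset_tag: str = ""

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2:
            raise ParameterError("signal must be 2-D (channels x samples)")
        if self.signal.shape[0] != len(self.channels):
            raise ParameterError(
                f"signal has {self.signal.shape[0]} rows but "
                f"{len(self.channels)} channel names"
            )
        if self.fs <= 0:
            raise ParameterError("fs must be positive")
        if not np.all(np.isfinite(self.signal)):
            raise ParameterError("signal contains non-finite values")
        if self.group not in LABELS:
            raise ParameterError(f"group must be one of {LABELS}, got {self.group!r}")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, **kw) -> "Recording":
        args = dict(
            subject_id=self.subject_id,
            group=self.group,
            fs=self.fs,
            channels=list(self.channels),
            signal=self.signal.copy(),
            dataset_tag=self.dataset_tag,
        )
        args.update(kw)
        return Recording(**args)


@dataclass
class Segment:
    """One fixed-length analysis window (channels x samples)."""

    subject_id: str
    label: str
    window: np.ndarray
    t0: float
    fs: float

    def __post_init__(self) -> None:
        self.window = np.asarray(self.window, dtype=np.float64)
        if self.window.ndim != 2:
            raise ParameterError("window must be 2-D")
        if not np.all(np.isfinite(self.window)):
            raise ParameterError("window contains non-finite values")


@dataclass
class FeatureSet:
    """Paired time-frequency (F1) and spatial (F2) features for one segment.

    F1: channels x bands x time-steps, F2: components x time-steps;
    after :func:`mdefusion.features.build_feature_set` the two time axes
    are aligned to the same length.
    """

    F1: np.ndarray
    F2: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.F1 = np.asarray(self.F1, dtype=np.float64)
        self.F2 = np.asarray(self.F2, dtype=np.float64)
        if not (np.all(np.isfinite(self.F1)) and np.all(np.isfinite(self.F2))):
            raise ParameterError("features contain non-finite values")
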