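"""Time-frequency (wavelet) and spatial (ICA) feature extraction.

F1 — per channel, a wavelet-packet decomposition (default db4, depth 3,
periodization mode, hence orthonormal: coefficient energy equals signal
energy) giving ``2**depth`` frequency-ordered subband coefficient
sequences. A ``cwt`` mode is also provided: the direct scale-and-shift
inner product with a real Morlet mother wavelet,

    F1[s, x] = (1/sqrt(beta_s)) * sum_t  x(t) * psi((t - x)/beta_s)

with unit sample spacing.

F2 — the activations of a spatial unmixing matrix J estimated by
fixed-point ICA (tanh/log-cosh contrast, deflation) on the *training*
partition only; J is then applied unchanged everywhere (F2 = J X).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pywt
from sklearn.decomposition import FastICA

from .types import (DegenerateInputError, FeatureSet, ParameterError, Segment)


def _window_array(window) -> np.ndarray:
    arr = window.window if isinstance(window, Segment) else np.asarray(window, float)
    if arr.ndim != 2:
        raise ParameterError("window must be channels x samples")
    return arr


def morlet(u: np.ndarray, w0: float = 5.0) -> np.ndarray:
    """Real Morlet mother wavelet exp(-u^2/2) cos(w0 u)."""
    u = np.asarray(u, dtype=float)
    return np.exp(-0.5 * u ** 2) * np.cos(w0 * u)


def wavelet_time_frequency(window, mode: str = "wpt", wavelet: str = "db4",
                           depth_or_scales=3) -> np.ndarray:
    """Extract per-channel time-frequency coefficients.

    wpt mode returns (channels, 2**depth, T / 2**depth); cwt mode returns
    (channels, n_scales, T).
    """
    x = _window_array(window)
    n_ch, n = x.shape
    if mode == "wpt":
        depth = int(depth_or_scales)
        if 2 ** depth > n:
            raise ParameterError(f"depth {depth} too large for window of {n} samples")
        out = []
        for c in range(n_ch):
            wp = pywt.WaveletPacket(data=x[c], wavelet=wavelet,
                                    mode="periodization", maxlevel=depth)
            nodes = wp.get_level(depth, order="freq")
            out.append(np.stack([nd.data for nd in nodes]))
        return np.stack(out)
    if mode == "cwt":
        scales = np.atleast_1d(np.asarray(depth_or_scales, dtype=float))
        if np.any(scales <= 0):
            raise ParameterError("scales must be positive")
        out = np.empty((n_ch, scales.size, n))
        t = np.arange(n, dtype=float)
        for si, beta in enumerate(scales):
            # kernel support where the Gaussian envelope is non-negligible
            half = int(np.ceil(5.0 * beta))
            u = np.arange(-half, half + 1, dtype=float)
            kern = morlet(u / beta) / np.sqrt(beta)
            for c in range(n_ch):
                # coef[chi] = sum_t x[t] * psi((t - chi)/beta)/sqrt(beta)
                out[c, si] = np.correlate(np.pad(x[c], half), kern, mode="valid")
        return out
    raise ParameterError(f"unknown mode {mode!r} (use 'wpt' or 'cwt')")


def wavelet_reconstruct(coeffs: np.ndarray, wavelet: str = "db4") -> np.ndarray:
    """Invert a wpt-mode decomposition (orthonormal, so exact)."""
    n_ch, n_bands, _ = coeffs.shape
    depth = int(np.log2(n_bands))
    out = []
    for c in range(n_ch):
        wp = pywt.WaveletPacket(data=None, wavelet=wavelet,
                                mode="periodization", maxlevel=depth)
        # nodes in frequency order must be written back under their natural paths
        tmpl = pywt.WaveletPacket(data=np.zeros(coeffs.shape[2] * n_bands),
                                  wavelet=wavelet, mode="periodization",
                                  maxlevel=depth)
        paths = [nd.path for nd in tmpl.get_level(depth, order="freq")]
        for b, path in enumerate(paths):
            wp[path] = coeffs[c, b]
        out.append(wp.reconstruct(update=False))
    return np.stack(out)


@dataclass(frozen=True)
class UnmixingModel:
    """Fitted spatial unmixing: F2 = J (X - mean)."""

    J: np.ndarray              # components x channels
    mean: np.ndarray           # per-channel mean removed before unmixing
    whitening: np.ndarray      # whitening matrix from the ICA fit
    fitted_on: str = "train"

    def __post_init__(self) -> None:
        J = np.asarray(self.J, float)
        if J.ndim != 2 or J.shape[0] > J.shape[1]:
            raise ParameterError("J must be components x channels, components <= channels")
        if np.linalg.matrix_rank(J) < J.shape[0]:
            raise DegenerateInputError("unmixing matrix is rank deficient")

    @property
    def n_components(self) -> int:
        return self.J.shape[0]

    @property
    def n_channels(self) -> int:
        return self.J.shape[1]


def fit_ica(train_segments: Sequence, n_components: Optional[int] = None,
            seed: int = 0, max_samples: int = 50_000,
            max_iter: int = 500) -> UnmixingModel:
    """Fit fixed-point ICA on pooled training segments.

    Segments are concatenated along time (subsampled to ``max_samples``
    time points for tractability) and a single unmixing matrix is
    estimated; it is applied unchanged to every partition downstream.
    """
    arrays = [_window_array(s) for s in train_segments]
    if not arrays:
        raise ParameterError("no training segments provided")
    n_ch = arrays[0].shape[0]
    if any(a.shape[0] != n_ch for a in arrays):
        raise ParameterError("segments disagree on channel count")
    if n_components is not None and n_components > n_ch:
        raise ParameterError(f"n_components={n_components} exceeds {n_ch} channels")
    X = np.concatenate(arrays, axis=1).T      # samples x channels
    if X.shape[0] <= n_ch:
        raise ParameterError("need more pooled samples than channels")
    rng = np.random.default_rng(seed)
    if X.shape[0] > max_samples:
        X = X[np.sort(rng.choice(X.shape[0], max_samples, replace=False))]
    cov_rank = int(np.linalg.matrix_rank(np.cov(X.T)))
    if n_components is None:
        # interpolated channels are linear combinations of measured ones, so
        # harmonized montages are rank-deficient; whiten only to the rank
        n_components = min(n_ch, cov_rank)
    if cov_rank < n_components:
        raise DegenerateInputError(
            f"pooled covariance rank {cov_rank} < requested {n_components} components")
    ica = FastICA(n_components=n_components, algorithm="deflation", fun="logcosh",
                  whiten="unit-variance", max_iter=max_iter, tol=1e-4,
                  random_state=int(seed) % (2 ** 32))
    ica.fit(X)
    return UnmixingModel(J=ica.components_.copy(), mean=ica.mean_.copy(),
                         whitening=ica.whitening_.copy(), fitted_on="train")


def ica_spatial(window, model: UnmixingModel) -> np.ndarray:
    """F2 = J (X - mean): unmixed source activations, components x samples."""
    x = _window_array(window)
    if x.shape[0] != model.n_channels:
        raise ParameterError(
            f"window has {x.shape[0]} channels, model expects {model.n_channels}")
    return model.J @ (x - model.mean[:, None])


def align_f1(F1: np.ndarray, n_steps: int) -> np.ndarray:
    """Resample F1's subband time axis to ``n_steps`` by nearest-index mapping."""
    n_sub = F1.shape[2]
    idx = np.minimum((np.floor((np.arange(n_steps) + 0.5) * n_sub / n_steps)).astype(int),
                     n_sub - 1)
    return F1[:, :, idx]


def build_feature_set(window, model: UnmixingModel, mode: str = "wpt",
                      wavelet: str = "db4", depth_or_scales=3,
                      ica_seed: int = 0) -> FeatureSet:
    """Bundle time-aligned F1 and F2 for one segment."""
    F1 = wavelet_time_frequency(window, mode=mode, wavelet=wavelet,
                                depth_or_scales=depth_or_scales)
    F2 = ica_spatial(window, model)
    F1 = align_f1(F1, F2.shape[1])
    return FeatureSet(F1=F1, F2=F2, meta={
        "mode": mode, "wavelet": wavelet,
        "depth": depth_or_scales if mode == "wpt" else None,
        "ica_seed": ica_seed,
    })


@dataclass
class FeatureScaler:
    """Per-feature z-scoring with statistics from the training partition.

    F1 is scaled per (channel, band); F2 per component; statistics pool
    over segments and time.
    """

    f1_mean: np.ndarray = None
    f1_sd: np.ndarray = None
    f2_mean: np.ndarray = None
    f2_sd: np.ndarray = None

    def fit(self, feature_sets: Sequence[FeatureSet]) -> "FeatureScaler":
        if not feature_sets:
            raise ParameterError("no feature sets to fit scaler on")
        F1 = np.stack([fs.F1 for fs in feature_sets])   # (N, C, B, T)
        F2 = np.stack([fs.F2 for fs in feature_sets])   # (N, K, T)
        self.f1_mean = F1.mean(axis=(0, 3))
        self.f1_sd = np.maximum(F1.std(axis=(0, 3)), 1e-12)
        self.f2_mean = F2.mean(axis=(0, 2))
        self.f2_sd = np.maximum(F2.std(axis=(0, 2)), 1e-12)
        return self

    def transform(self, fs: FeatureSet) -> FeatureSet:
        if self.f1_mean is None:
            raise ParameterError("scaler not fitted")
        F1 = (fs.F1 - self.f1_mean[:, :, None]) / self.f1_sd[:, :, None]
        F2 = (fs.F2 - self.f2_mean[:, None]) / self.f2_sd[:, None]
        return FeatureSet(F1=F1, F2=F2, meta=dict(fs.meta))
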