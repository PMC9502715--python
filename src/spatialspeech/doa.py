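"""Probabilistic direction-of-arrival estimation from GCC-PHAT features.

Per STFT-like frame, phase-transform-whitened generalized cross-correlation
functions are computed for every microphone pair of a channel subset,
restricted to the physically plausible delay range, and concatenated into a
feature vector phi(t).  One linear max-margin classifier per azimuth sector
gives decision values D(alpha, t) = <w(alpha), phi(t)> + b(alpha), which a
single shared logistic calibration maps to source-presence probabilities

    P(alpha, t) = 1 / (1 + exp(-(beta1 + beta2 * D(alpha, t)))).

No normalization across alpha is applied: each sector carries its own
presence probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.svm import LinearSVC

from .core import (
    DEFAULT_AZIMUTH_GRID,
    FRONT_REAR_SUBSET,
    ArrayGeometry,
    DirectionProfile,
    MultichannelSignal,
)
from .scene import SceneSpec, build_scene

__all__ = [
    "GccFeature",
    "DoaModel",
    "SpatialProbabilityMap",
    "gcc_phat_pair",
    "extract_features",
    "gcc_feature_matrix",
    "default_tau_max",
    "train_doa_model",
    "make_training_set",
    "train_default_model",
    "probability_map",
    "average_map",
]

SPECTRAL_FLOOR = 1e-12
TRAINING_SNRS_DB = (-15.0, 0.0, 15.0)


@dataclass
class GccFeature:
    """Concatenated GCC-PHAT values for one frame."""

    values: np.ndarray
    frame_index: int
    pair_layout: list  # ordered (k, l, tau_grid) per pair
    degenerate: bool = False


@dataclass
class SpatialProbabilityMap:
    """P(alpha, t): sectors x frames source-presence probabilities."""

    probs: np.ndarray
    azimuth_grid: np.ndarray
    frame_hop_s: float

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[0] != len(self.azimuth_grid):
            raise ValueError("probs must be (sectors, frames)")
        if self.probs.size and (self.probs.min() <= 0 or self.probs.max() >= 1):
            raise ValueError("probabilities must lie strictly in (0, 1)")


@dataclass
class DoaModel:
    """Per-sector linear classifiers plus a shared logistic calibration."""

    azimuth_grid: np.ndarray
    weights: np.ndarray  # (R, D)
    biases: np.ndarray  # (R,)
    beta1: float
    beta2: float
    frame_s: float = 0.025
    hop_s: float = 0.010
    tau_max: int = 11
    channel_subset: tuple = FRONT_REAR_SUBSET
    sample_rate: int = 16000

    def decision_values(self, features: np.ndarray) -> np.ndarray:
        """D(alpha, t) for a (frames, D) feature matrix -> (R, frames)."""
        return (features @ self.weights.T + self.biases).T

    def calibrate(self, decisions: np.ndarray) -> np.ndarray:
        from scipy.special import expit

        return expit(self.beta1 + self.beta2 * decisions)

    def save(self, path) -> None:
        np.savez(
            path,
            azimuth_grid=self.azimuth_grid,
            weights=self.weights,
            biases=self.biases,
            beta=np.array([self.beta1, self.beta2]),
            params=np.array([self.frame_s, self.hop_s, self.tau_max, self.sample_rate]),
            channel_subset=np.array(self.channel_subset),
        )

    @classmethod
    def load(cls, path) -> "DoaModel":
        z = np.load(path)
        frame_s, hop_s, tau_max, sr = z["params"]
        return cls(
            azimuth_grid=z["azimuth_grid"],
            weights=z["weights"],
            biases=z["biases"],
            beta1=float(z["beta"][0]),
            beta2=float(z["beta"][1]),
            frame_s=float(frame_s),
            hop_s=float(hop_s),
            tau_max=int(tau_max),
            channel_subset=tuple(int(c) for c in z["channel_subset"]),
            sample_rate=int(sr),
        )


def default_tau_max(geometry: ArrayGeometry) -> int:
    """Plausible delay range in samples: aperture travel time + 2 guard samples."""
    return geometry.max_delay_samples()


def gcc_phat_pair(
    frame_k: np.ndarray, frame_l: np.ndarray, tau_max: int, n_fft: int | None = None
) -> tuple[np.ndarray, bool]:
    """PHAT-weighted cross-correlation of two windowed frames.

    Returns (rho, degenerate): rho indexed tau = -tau_max .. +tau_max, with
    rho(tau) peaking where frame_k lags frame_l by tau samples.  All-zero
    frames give a zero vector with the degenerate flag set.
    """
    frame_k = np.asarray(frame_k, dtype=float)
    frame_l = np.asarray(frame_l, dtype=float)
    if frame_k.shape != frame_l.shape:
        raise ValueError("frames must have equal length")
    if tau_max < 1:
        raise ValueError("tau_max must be >= 1")
    if n_fft is None:
        n_fft = int(2 ** np.ceil(np.log2(frame_k.size)))
    Xk = np.fft.rfft(frame_k, n=n_fft)
    Xl = np.fft.rfft(frame_l, n=n_fft)
    cross = Xk * np.conj(Xl)
    mag = np.abs(cross)
    degenerate = bool(mag.max() < SPECTRAL_FLOOR)
    whitened = cross / np.maximum(mag, SPECTRAL_FLOOR)
    if degenerate:
        return np.zeros(2 * tau_max + 1), True
    rho = np.fft.irfft(whitened, n=n_fft)
    return np.concatenate([rho[-tau_max:], rho[: tau_max + 1]]), False


def _frame_signal(x: np.ndarray, frame_len: int, hop: int) -> np.ndarray:
    n_frames = (x.shape[-1] - frame_len) // hop + 1
    if n_frames < 1:
        raise ValueError("frame longer than signal")
    idx = np.arange(frame_len)[None, :] + hop * np.arange(n_frames)[:, None]
    return x[..., idx]  # (..., n_frames, frame_len)


def gcc_feature_matrix(
    signal: MultichannelSignal,
    channel_subset: tuple | None = None,
    frame_s: float = 0.025,
    hop_s: float = 0.010,
    tau_max: int | None = None,
) -> tuple[np.ndarray, list]:
    """Vectorized GCC-PHAT feature extraction.

    Returns ((frames, D) matrix, pair_layout) where D = n_pairs*(2*tau_max+1)
    and pairs run in lexicographic channel order.
    """
    subset = _resolve_subset(signal, channel_subset)
    if tau_max is None:
        tau_max = default_tau_max(signal.geometry)
    sr = signal.sample_rate
    frame_len = int(round(frame_s * sr))
    hop = int(round(hop_s * sr))
    n_fft = int(2 ** np.ceil(np.log2(frame_len)))
    frames = _frame_signal(signal.samples[list(subset)], frame_len, hop)
    frames = frames * np.hanning(frame_len)
    X = np.fft.rfft(frames, n=n_fft, axis=-1)  # (C, T, F)
    tau_grid = np.arange(-tau_max, tau_max + 1)
    pairs = [(k, l) for i, k in enumerate(subset) for l in subset[i + 1 :]]
    blocks = []
    layout = []
    for idx_k, idx_l in ((subset.index(k), subset.index(l)) for k, l in pairs):
        cross = X[idx_k] * np.conj(X[idx_l])
        mag = np.abs(cross)
        whitened = np.where(mag < SPECTRAL_FLOOR, 0.0, cross / np.maximum(mag, SPECTRAL_FLOOR))
        rho = np.fft.irfft(whitened, n=n_fft, axis=-1)
        blocks.append(np.concatenate([rho[:, -tau_max:], rho[:, : tau_max + 1]], axis=1))
    for k, l in pairs:
        layout.append((k, l, tau_grid.copy()))
    return np.concatenate(blocks, axis=1), layout


def _resolve_subset(signal: MultichannelSignal, channel_subset) -> tuple:
    if channel_subset is None:
        subset = FRONT_REAR_SUBSET if signal.n_channels == 6 else tuple(range(signal.n_channels))
    else:
        subset = tuple(channel_subset)
    if len(subset) < 2:
        raise ValueError("need at least 2 channels for GCC features")
    return subset


def extract_features(
    signal: MultichannelSignal,
    channel_subset: tuple | None = None,
    frame_s: float = 0.025,
    hop_s: float = 0.010,
    tau_max: int | None = None,
) -> list[GccFeature]:
    """Per-frame GccFeature objects (see :func:`gcc_feature_matrix`)."""
    matrix, layout = gcc_feature_matrix(signal, channel_subset, frame_s, hop_s, tau_max)
    return [
        GccFeature(row, i, layout, degenerate=bool(np.all(row == 0)))
        for i, row in enumerate(matrix)
    ]


def train_doa_model(
    features: np.ndarray,
    sector_labels: np.ndarray,
    azimuth_grid: np.ndarray = DEFAULT_AZIMUTH_GRID,
    C: float = 1.0,
    seed: int = 0,
    **feature_params,
) -> DoaModel:
    """Fit one-vs-rest linear SVMs per sector plus the logistic calibration.

    ``sector_labels`` are azimuth values on ``azimuth_grid``.  The
    calibration (beta1, beta2) is fitted to pooled decision values against
    binary sector-correctness labels (Platt-style, one global pair).
    """
    features = np.asarray(features, dtype=float)
    sector_labels = np.asarray(sector_labels, dtype=float)
    grid = np.asarray(azimuth_grid, dtype=float)
    present = np.unique(sector_labels)
    missing = [a for a in grid if not np.any(np.isclose(present, a))]
    if missing:
        raise ValueError(f"sectors with no training examples: {missing}")
    if len(present) < 2:
        raise ValueError("need at least 2 sectors represented")
    label_idx = np.argmin(np.abs(sector_labels[:, None] - grid[None, :]), axis=1)
    svm = LinearSVC(C=C, random_state=seed)
    svm.fit(features, label_idx)
    # LinearSVC orders coef_ by sorted class label; map back onto the grid.
    # With exactly two sectors it returns a single hyperplane (positive class
    # second); expand it to one signed (w, b) per sector.
    weights = np.zeros((len(grid), features.shape[1]))
    biases = np.zeros(len(grid))
    if len(svm.classes_) == 2 and svm.coef_.shape[0] == 1:
        neg, pos = (int(c) for c in svm.classes_)
        weights[pos], biases[pos] = svm.coef_[0], svm.intercept_[0]
        weights[neg], biases[neg] = -svm.coef_[0], -svm.intercept_[0]
    else:
        for row, cls in enumerate(svm.classes_):
            weights[int(cls)] = svm.coef_[row]
            biases[int(cls)] = svm.intercept_[row]
    decisions = features @ weights.T + biases  # (N, R)
    correct = (label_idx[:, None] == np.arange(len(grid))[None, :]).astype(int)
    lr = LogisticRegression(C=1e6, random_state=seed)
    lr.fit(decisions.reshape(-1, 1), correct.ravel())
    beta2 = float(lr.coef_[0, 0])
    beta1 = float(lr.intercept_[0])
    return DoaModel(
        azimuth_grid=grid, weights=weights, biases=biases,
        beta1=beta1, beta2=beta2, **feature_params,
    )


def make_training_set(
    geometry: ArrayGeometry,
    azimuth_grid: np.ndarray = DEFAULT_AZIMUTH_GRID,
    snrs_db: tuple = TRAINING_SNRS_DB,
    duration_s: float = 2.0,
    seed: int = 0,
    channel_subset: tuple | None = None,
    tau_max: int | None = None,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Training scenes per the reference recipe: one speech-like source per
    sector in anechoic diffuse noise at SNRs of -15, 0 and +15 dB."""
    feats, labels = [], []
    scene_seed = seed
    for az in azimuth_grid:
        for snr in snrs_db:
            scene_seed += 1
            spec = SceneSpec(
                snr_db=float(snr), seed=scene_seed, target_azimuth_deg=float(az),
                noise_kind="diffuse", room="anechoic", duration_s=duration_s,
            )
            sig, _ = build_scene(spec, geometry)
            m, _ = gcc_feature_matrix(sig, channel_subset, tau_max=tau_max)
            feats.append(m)
            labels.append(np.full(m.shape[0], float(az)))
    params = {
        "channel_subset": _resolve_subset_geom(geometry, channel_subset),
        "tau_max": tau_max if tau_max is not None else default_tau_max(geometry),
        "sample_rate": geometry.sample_rate,
    }
    return np.concatenate(feats), np.concatenate(labels), params


def _resolve_subset_geom(geometry: ArrayGeometry, channel_subset) -> tuple:
    if channel_subset is not None:
        return tuple(channel_subset)
    return FRONT_REAR_SUBSET if geometry.n_mics == 6 else tuple(range(geometry.n_mics))


def train_default_model(
    geometry: ArrayGeometry,
    seed: int = 0,
    azimuth_grid: np.ndarray = DEFAULT_AZIMUTH_GRID,
    duration_s: float = 2.0,
) -> DoaModel:
    """End-to-end convenience: synthesize the training set and fit the model."""
    X, y, params = make_training_set(
        geometry, azimuth_grid, duration_s=duration_s, seed=seed
    )
    return train_doa_model(X, y, azimuth_grid, seed=seed, **params)


def probability_map(signal: MultichannelSignal, model: DoaModel) -> SpatialProbabilityMap:
    """Frame-wise source-presence probability per sector."""
    if len(model.azimuth_grid) == 0:
        raise ValueError("model sector grid is empty")
    if signal.sample_rate != model.sample_rate:
        raise ValueError("signal sample rate does not match the trained model")
    if max(model.channel_subset) >= signal.n_channels:
        raise ValueError("signal has fewer channels than the model's subset")
    feats, _ = gcc_feature_matrix(
        signal, model.channel_subset, model.frame_s, model.hop_s, model.tau_max
    )
    if feats.shape[1] != model.weights.shape[1]:
        raise ValueError("feature layout mismatch with the trained model")
    probs = model.calibrate(model.decision_values(feats))
    probs = np.clip(probs, 1e-12, 1 - 1e-12)
    return SpatialProbabilityMap(probs, model.azimuth_grid, model.hop_s)


def average_map(pmap: SpatialProbabilityMap) -> DirectionProfile:
    """Time average: P_DOA(alpha) = (1/T) sum_t P(alpha, t)."""
    if pmap.probs.shape[1] < 1:
        raise ValueError("empty probability map")
    return DirectionProfile(
        pmap.probs.mean(axis=1), pmap.azimuth_grid, kind="P_DOA"
    )
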