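"""Frequency-domain MVDR beamforming over a steering grid.

Free-field plane-wave steering vectors (reference channel normalized to 1),
an isotropic noise covariance built by averaging steering outer products
over a full horizontal circle, and the classic MVDR solution

    w(alpha, omega) = R^-1 d / (d^H R^-1 d),

applied per STFT bin with a square-root-Hann analysis/synthesis pair
(perfect reconstruction at 50% overlap).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import ShortTimeFFT
from scipy.signal.windows import hann

from .core import DEFAULT_AZIMUTH_GRID, ArrayGeometry, MultichannelSignal

__all__ = [
    "SteeringVectorSet",
    "NoiseCovariance",
    "BeamformerBank",
    "steering_vectors",
    "isotropic_covariance",
    "mvdr_weights",
    "design_beamformer",
    "beamform_all",
    "DEFAULT_N_FFT",
    "REFERENCE_CHANNEL",
]

DEFAULT_N_FFT = 512
DEFAULT_LOADING = 1e-3
REFERENCE_CHANNEL = 0  # front-left microphone
ISOTROPIC_GRID = np.arange(-180.0, 180.0, 5.0)  # 72 directions


@dataclass
class SteeringVectorSet:
    """d(alpha, omega): (n_azimuths, n_bins, n_mics), reference element = 1."""

    vectors: np.ndarray
    azimuth_grid: np.ndarray
    frequencies_hz: np.ndarray
    n_fft: int
    reference_channel: int = REFERENCE_CHANNEL

    def __post_init__(self) -> None:
        ref = self.vectors[..., self.reference_channel]
        if not np.allclose(ref, 1.0, atol=1e-10):
            raise ValueError("reference channel must be normalized to 1")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("steering vectors must be finite")


@dataclass
class NoiseCovariance:
    """R(omega): (n_bins, M, M) Hermitian, positive definite after loading."""

    matrices: np.ndarray
    frequencies_hz: np.ndarray
    loading: float

    def __post_init__(self) -> None:
        herm_err = np.abs(self.matrices - self.matrices.conj().transpose(0, 2, 1)).max()
        if herm_err > 1e-10:
            raise ValueError(f"covariance not Hermitian (max deviation {herm_err:.2e})")


@dataclass
class BeamformerBank:
    """w(alpha, omega): (n_azimuths, n_bins, n_mics) MVDR weights."""

    weights: np.ndarray
    azimuth_grid: np.ndarray
    frequencies_hz: np.ndarray
    n_fft: int
    reference_channel: int = REFERENCE_CHANNEL


def steering_vectors(
    geometry: ArrayGeometry,
    azimuth_grid: np.ndarray = DEFAULT_AZIMUTH_GRID,
    n_fft: int = DEFAULT_N_FFT,
    reference_channel: int = REFERENCE_CHANNEL,
    impulse_responses: np.ndarray | None = None,
) -> SteeringVectorSet:
    """Free-field steering vectors d_m = exp(-i omega (tau_m - tau_ref)).

    When ``impulse_responses`` ((n_azimuths, M, L) measured IRs) is given,
    d is their frequency response normalized to the reference channel.
    """
    grid = np.asarray(azimuth_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("azimuth grid must be nonempty")
    freqs = np.fft.rfftfreq(n_fft, 1.0 / geometry.sample_rate)
    if impulse_responses is not None:
        irs = np.asarray(impulse_responses)
        if irs.shape[0] != grid.size or irs.shape[1] != geometry.n_mics:
            raise ValueError("impulse responses must be (n_azimuths, M, L)")
        H = np.fft.rfft(irs, n=n_fft, axis=-1)  # (A, M, F)
        ref = H[:, reference_channel : reference_channel + 1, :]
        d = (H / np.where(np.abs(ref) < 1e-12, 1e-12, ref)).transpose(0, 2, 1)
    else:
        taus = np.stack([geometry.delays(a) for a in grid])  # (A, M)
        taus = taus - taus[:, reference_channel : reference_channel + 1]
        d = np.exp(-2j * np.pi * freqs[None, :, None] * taus[:, None, :])
    return SteeringVectorSet(d, grid, freqs, n_fft, reference_channel)


def isotropic_covariance(
    steering: SteeringVectorSet, loading: float = DEFAULT_LOADING
) -> NoiseCovariance:
    """R(omega) = mean_alpha d d^H + loading * tr(R)/M * I.

    ``steering`` must cover the full horizontal circle (>= 36 directions)
    so the average models a (head-related) isotropic noise field.
    """
    if loading <= 0:
        raise ValueError("diagonal loading must be positive")
    grid = steering.azimuth_grid
    if grid.size < 36 or (grid.max() - grid.min()) < 270.0:
        raise ValueError("isotropic covariance needs a full-circle grid (>= 36 directions)")
    d = steering.vectors  # (A, F, M)
    R = np.einsum("afm,afn->fmn", d, d.conj()) / grid.size
    M = R.shape[-1]
    tr = np.einsum("fmm->f", R).real
    R = R + (loading * tr / M)[:, None, None] * np.eye(M)
    return NoiseCovariance(R, steering.frequencies_hz, loading)


def mvdr_weights(d: np.ndarray, R: np.ndarray) -> np.ndarray:
    """MVDR solution for a single (d, R) pair or stacked bins.

    ``d``: (..., M), ``R``: (..., M, M).  Raises naming the bin when R is
    singular.
    """
    d = np.asarray(d)
    R = np.asarray(R)
    try:
        Rinv_d = np.linalg.solve(R, d[..., None])[..., 0]
    except np.linalg.LinAlgError:
        flat = R.reshape(-1, R.shape[-1], R.shape[-1])
        for i, Ri in enumerate(flat):
            if np.linalg.matrix_rank(Ri) < Ri.shape[0]:
                raise np.linalg.LinAlgError(f"singular noise covariance at bin {i}")
        raise
    denom = np.einsum("...m,...m->...", d.conj(), Rinv_d)
    return Rinv_d / denom[..., None]


def design_beamformer(
    geometry: ArrayGeometry,
    azimuth_grid: np.ndarray = DEFAULT_AZIMUTH_GRID,
    n_fft: int = DEFAULT_N_FFT,
    loading: float = DEFAULT_LOADING,
    reference_channel: int = REFERENCE_CHANNEL,
) -> BeamformerBank:
    """Steering grid + isotropic covariance -> MVDR weight bank."""
    steer = steering_vectors(geometry, azimuth_grid, n_fft, reference_channel)
    iso = steering_vectors(geometry, ISOTROPIC_GRID, n_fft, reference_channel)
    cov = isotropic_covariance(iso, loading)
    # broadcast R over azimuths: weights per (alpha, bin)
    w = np.stack([mvdr_weights(steer.vectors[a], cov.matrices)
                  for a in range(len(steer.azimuth_grid))])
    return BeamformerBank(w, steer.azimuth_grid, steer.frequencies_hz, n_fft,
                          reference_channel)


def _stft_pair(n_fft: int, sample_rate: int) -> ShortTimeFFT:
    win = np.sqrt(hann(n_fft, sym=False))
    return ShortTimeFFT(win, hop=n_fft // 2, fs=sample_rate, fft_mode="onesided")


def beamform_all(signal: MultichannelSignal, bank: BeamformerBank) -> np.ndarray:
    """Apply every steering direction: returns (n_azimuths, n_samples).

    Y(omega, t) = w^H(alpha, omega) X(omega, t), resynthesized with the
    COLA-compliant square-root-Hann pair.
    """
    if signal.n_channels != bank.weights.shape[-1]:
        raise ValueError("channel count does not match beamformer weights")
    sft = _stft_pair(bank.n_fft, signal.sample_rate)
    X = sft.stft(signal.samples, axis=-1)  # (C, F, T)
    if X.shape[1] != bank.weights.shape[1]:
        raise ValueError("STFT bin grid does not match the beamformer bank")
    out = np.empty((len(bank.azimuth_grid), signal.n_samples))
    for a in range(len(bank.azimuth_grid)):
        Y = np.einsum("cf,cft->ft", bank.weights[a].conj().T, X)
        out[a] = sft.istft(Y, k1=signal.n_samples).real
    return out
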