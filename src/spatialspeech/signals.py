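"""Single-channel signal synthesis primitives.

Everything here is deterministic under a fixed seed and produces plain
float64 waveforms.  The phone-template machinery is shared by the scene
simulator (speech-like target source) and the posteriorgram module
(labelled phone streams for training the classifier): each phone class is
a fixed spectral template — a harmonic source through formant-like
resonators for voiced classes, a band-passed noise burst for fricative-like
classes — so classes are acoustically distinct and learnable.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

__all__ = [
    "PHONE_LABELS",
    "SILENCE_LABEL",
    "phone_inventory",
    "render_phone",
    "phone_stream",
    "speech_shaped_noise",
    "modulation_index",
    "spectral_flatness",
]

# 40 speech-like classes (ARPABET-style names) + silence.
PHONE_LABELS = [
    "aa", "ae", "ah", "ao", "aw", "ay", "b", "ch", "d", "dh",
    "dx", "eh", "er", "ey", "f", "g", "hh", "ih", "iy", "jh",
    "k", "l", "m", "n", "ng", "ow", "oy", "p", "r", "s",
    "sh", "t", "th", "uh", "uw", "v", "w", "y", "z", "zh",
]
SILENCE_LABEL = "sil"

_N_VOICED = 26  # first 26 class indices are rendered as voiced


def phone_inventory() -> list[str]:
    """Default inventory: 40 phone classes plus silence (last)."""
    return PHONE_LABELS + [SILENCE_LABEL]


def _class_params(idx: int) -> dict:
    """Deterministic acoustic template for phone class ``idx``.

    Voiced classes tile an (f1, f2) formant grid; unvoiced classes tile
    band-pass centres from 1 to 7 kHz.  Parameters depend only on the
    class index, never on a stream seed, so templates are stable across
    training and test material.
    """
    if idx < _N_VOICED:
        row, col = divmod(idx, 6)
        f1 = 260.0 + 130.0 * col  # 260 .. 910 Hz
        f2 = 950.0 + 330.0 * row  # 950 .. 2270 Hz
        return {
            "voiced": True,
            "f0": 95.0 + 5.0 * idx,
            "formants": (f1, f2 + 45.0 * col),
        }
    j = idx - _N_VOICED
    centre = 1000.0 + 430.0 * j  # 1.0 .. 6.6 kHz
    return {"voiced": False, "centre": centre, "bw": 400.0 + 40.0 * j}


def _resonator(f_hz: float, sr: int, r: float = 0.97):
    """Second-order all-pole resonator coefficients."""
    w = 2 * np.pi * f_hz / sr
    return [1.0], [1.0, -2 * r * np.cos(w), r * r]


def render_phone(idx: int, n_samples: int, sr: int, rng: np.random.Generator) -> np.ndarray:
    """Render one realisation of phone class ``idx`` (RMS approx 0.1)."""
    if n_samples <= 0:
        return np.zeros(0)
    p = _class_params(idx)
    if p["voiced"]:
        # glottal-like pulse train with small period jitter
        f0 = p["f0"] * (1.0 + 0.03 * rng.standard_normal())
        period = max(2, int(round(sr / f0)))
        x = np.zeros(n_samples)
        pos = int(rng.integers(0, period))
        while pos < n_samples:
            x[pos] = 1.0
            pos += period + int(rng.integers(-1, 2))
        for f in p["formants"]:
            b, a = _resonator(f, sr)
            x = sps.lfilter(b, a, x)
        x += 0.02 * rng.standard_normal(n_samples)
    else:
        sos = sps.butter(
            4,
            [max(50.0, p["centre"] - p["bw"]), min(sr / 2 - 50.0, p["centre"] + p["bw"])],
            btype="bandpass",
            fs=sr,
            output="sos",
        )
        x = sps.sosfilt(sos, rng.standard_normal(n_samples))
    rms = np.sqrt(np.mean(x**2))
    if rms > 0:
        x = 0.1 * x / rms
    ramp = min(int(0.005 * sr), n_samples // 2)
    if ramp > 0:
        w = 0.5 - 0.5 * np.cos(np.linspace(0, np.pi, ramp))
        x[:ramp] *= w
        x[-ramp:] *= w[::-1]
    return x


def phone_stream(
    duration_s: float,
    sample_rate: int,
    seed: int,
    n_classes: int = 40,
    silence_prob: float = 0.15,
    dur_range_s: tuple[float, float] = (0.04, 0.20),
) -> tuple[np.ndarray, np.ndarray]:
    """Random phone sequence as (waveform, per-sample class indices).

    Class index ``n_classes`` denotes silence.  Phone durations are drawn
    uniformly from ``dur_range_s`` (40-200 ms by default, below the ~300 ms
    ceiling of phonetic events); silence gaps are drawn from 60-250 ms.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    rng = np.random.default_rng(seed)
    n_total = int(round(duration_s * sample_rate))
    wave = np.zeros(n_total)
    labels = np.full(n_total, n_classes, dtype=int)
    pos = 0
    while pos < n_total:
        if rng.random() < silence_prob:
            idx = n_classes
            dur = rng.uniform(0.06, 0.25)
        else:
            idx = int(rng.integers(0, n_classes))
            dur = rng.uniform(*dur_range_s)
        n = min(int(round(dur * sample_rate)), n_total - pos)
        if idx < n_classes and n > 0:
            wave[pos : pos + n] = render_phone(idx, n, sample_rate, rng)
        labels[pos : pos + n] = idx
        pos += n
    return wave, labels


def speech_shaped_noise(n_samples: int, sample_rate: int, rng: np.random.Generator) -> np.ndarray:
    """Stationary noise with a long-term-speech-like spectrum.

    White Gaussian noise shaped in the frequency domain: flat to ~500 Hz,
    then rolling off at about -12 dB/octave.
    """
    x = rng.standard_normal(n_samples)
    X = np.fft.rfft(x)
    f = np.fft.rfftfreq(n_samples, 1.0 / sample_rate)
    H = 1.0 / (1.0 + (f / 500.0) ** 2)
    y = np.fft.irfft(X * H, n=n_samples)
    return 0.1 * y / np.sqrt(np.mean(y**2))


def modulation_index(x: np.ndarray, sample_rate: int, cutoff_hz: float = 30.0) -> float:
    """Envelope modulation depth: std/mean of the low-passed rectified signal."""
    sos = sps.butter(4, cutoff_hz, fs=sample_rate, output="sos")
    env = sps.sosfiltfilt(sos, np.abs(x))
    env = np.clip(env, 0.0, None)
    m = env.mean()
    return float(env.std() / m) if m > 0 else 0.0


def spectral_flatness(x: np.ndarray, sample_rate: int) -> float:
    """Geometric/arithmetic mean ratio of the Welch power spectrum."""
    _, psd = sps.welch(x, fs=sample_rate, nperseg=1024)
    psd = psd[1:]  # drop DC
    psd = np.clip(psd, 1e-30, None)
    return float(np.exp(np.mean(np.log(psd))) / np.mean(psd))
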