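"""Phoneme posteriorgrams: log-mel features, context stacking, a small
trainable frame classifier, and a parametric synthetic generator.

The classifier path (40-band log-mel, +/-5 frame context, feed-forward
softmax network) mirrors the front end of a hybrid ASR acoustic model at
desk scale.  The synthetic generator produces posteriorgrams of controlled
quality directly from label sequences — degradation ``delta`` mixes rows
toward uniform and ``smear_ms`` smooths activations over time, emulating
the temporal smearing seen for noisy speech — so every quality measure is
testable without any trained model.  Both paths emit the same
:class:`Posteriorgram` type.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.neural_network import MLPClassifier

from .signals import phone_inventory, phone_stream, speech_shaped_noise

__all__ = [
    "FRAME_LEN_S",
    "HOP_S",
    "N_MELS",
    "Posteriorgram",
    "PhonemeInventory",
    "logmel",
    "mel_filterbank",
    "stack_context",
    "synth_phone_stream",
    "synth_posteriorgram",
    "group_triphones",
    "train_phoneme_classifier",
    "PhonemeClassifier",
    "train_default_provider",
]

FRAME_LEN_S = 0.025  # Hamming window
HOP_S = 0.010
N_FFT = 512
N_MELS = 40
LOG_FLOOR = 1e-10


@dataclass
class PhonemeInventory:
    """Monophone labels plus an optional triphone -> monophone mapping."""

    labels: list[str] = field(default_factory=phone_inventory)
    triphone_map: dict | None = None

    def __post_init__(self) -> None:
        if self.triphone_map is not None:
            bad = set(self.triphone_map.values()) - set(self.labels)
            if bad:
                raise ValueError(f"triphone map targets outside inventory: {sorted(bad)}")

    @property
    def n_classes(self) -> int:
        return len(self.labels)


@dataclass
class Posteriorgram:
    """Frames x classes probability matrix with row sums of 1."""

    probs: np.ndarray
    labels: list[str]
    hop_s: float = HOP_S

    def __post_init__(self) -> None:
        self.probs = np.atleast_2d(np.asarray(self.probs, dtype=float))
        if self.probs.shape[1] != len(self.labels):
            raise ValueError("column count must match label count")
        if self.probs.min() < -1e-12 or self.probs.max() > 1 + 1e-9:
            raise ValueError("entries must lie in [0, 1]")
        sums = self.probs.sum(axis=1)
        if np.abs(sums - 1).max() > 1e-6:
            raise ValueError("rows must sum to 1 within 1e-6")

    @property
    def n_frames(self) -> int:
        return self.probs.shape[0]

    def to_csv(self, path) -> None:
        header = ",".join(self.labels)
        np.savetxt(path, self.probs, delimiter=",", header=header, comments="")

    @classmethod
    def from_csv(cls, path, hop_s: float = HOP_S) -> "Posteriorgram":
        with open(path) as fh:
            labels = fh.readline().strip().split(",")
        probs = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        return cls(probs, labels, hop_s)


def mel_filterbank(n_mels: int = N_MELS, n_fft: int = N_FFT, sample_rate: int = 16000) -> np.ndarray:
    """Triangular filters equidistant on the HTK mel scale: (n_mels, n_fft//2+1)."""
    def hz_to_mel(f):
        return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)

    def mel_to_hz(m):
        return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)

    edges_mel = np.linspace(hz_to_mel(0.0), hz_to_mel(sample_rate / 2), n_mels + 2)
    edges_hz = mel_to_hz(edges_mel)
    bins = np.fft.rfftfreq(n_fft, 1.0 / sample_rate)
    fb = np.zeros((n_mels, bins.size))
    for i in range(n_mels):
        lo, mid, hi = edges_hz[i : i + 3]
        up = (bins - lo) / (mid - lo)
        down = (hi - bins) / (hi - mid)
        fb[i] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


def logmel(waveform: np.ndarray, sample_rate: int = 16000) -> np.ndarray:
    """Log mel-filterbank features: (frames, 40).

    25 ms Hamming windows, 10 ms hop, 512-bin magnitude spectra grouped by
    40 triangular mel filters, log taken with a floor.
    """
    x = np.asarray(waveform, dtype=float).ravel()
    win_len = int(round(FRAME_LEN_S * sample_rate))
    hop = int(round(HOP_S * sample_rate))
    if x.size < win_len:
        raise ValueError("input shorter than one analysis window")
    n_frames = (x.size - win_len) // hop + 1
    idx = np.arange(win_len)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = x[idx] * np.hamming(win_len)
    mag = np.abs(np.fft.rfft(frames, n=N_FFT, axis=1))
    fb = mel_filterbank(N_MELS, N_FFT, sample_rate)
    return np.log(np.maximum(mag @ fb.T, LOG_FLOOR))


def n_feature_frames(n_samples: int, sample_rate: int = 16000) -> int:
    win_len = int(round(FRAME_LEN_S * sample_rate))
    hop = int(round(HOP_S * sample_rate))
    return (n_samples - win_len) // hop + 1


def stack_context(features: np.ndarray, left: int = 5, right: int = 5) -> np.ndarray:
    """Concatenate each frame with its temporal context (edges replicated).

    Output width = n_features * (left + right + 1); the default +/-5 frames
    turns 40 mel bands into 440-dimensional vectors.
    """
    if left < 0 or right < 0:
        raise ValueError("context sizes must be non-negative")
    feats = np.atleast_2d(np.asarray(features, dtype=float))
    if feats.shape[0] < 1:
        raise ValueError("need at least one frame")
    padded = np.concatenate(
        [np.repeat(feats[:1], left, axis=0), feats, np.repeat(feats[-1:], right, axis=0)]
    )
    T = feats.shape[0]
    return np.concatenate([padded[k : k + T] for k in range(left + right + 1)], axis=1)


def synth_phone_stream(
    inventory: PhonemeInventory, duration_s: float, seed: int, sample_rate: int = 16000
) -> tuple[np.ndarray, np.ndarray]:
    """Labelled synthetic phone audio: (waveform, per-frame class indices).

    Label count equals the log-mel frame count of the waveform; the label of
    a frame is the phone active at the frame centre.
    """
    if inventory.n_classes == 0:
        raise ValueError("empty inventory")
    n_classes = inventory.n_classes - 1  # last label is silence
    wave, sample_labels = phone_stream(duration_s, sample_rate, seed, n_classes=n_classes)
    win_len = int(round(FRAME_LEN_S * sample_rate))
    hop = int(round(HOP_S * sample_rate))
    n_frames = n_feature_frames(wave.size, sample_rate)
    centres = hop * np.arange(n_frames) + win_len // 2
    return wave, sample_labels[centres]


def synth_posteriorgram(
    labels: np.ndarray,
    delta: float,
    smear_ms: float,
    seed: int = 0,
    n_classes: int | None = None,
    class_labels: list[str] | None = None,
) -> Posteriorgram:
    """Parametric posteriorgram: one-hot rows, mixed with uniform by
    ``delta`` and smoothed over time by a ``smear_ms``-wide kernel.

    Both knobs emulate the degradations of noisy speech: ``delta`` reduces
    sparseness, ``smear_ms`` smears activations across frames.
    """
    if not 0.0 <= delta <= 1.0:
        raise ValueError("delta must lie in [0, 1]")
    if smear_ms < 0:
        raise ValueError("smear_ms must be non-negative")
    labels = np.asarray(labels, dtype=int)
    if class_labels is None:
        if n_classes is None:
            n_classes = int(labels.max()) + 1
        class_labels = [f"c{i}" for i in range(n_classes)]
    n_classes = len(class_labels)
    P = np.zeros((labels.size, n_classes))
    P[np.arange(labels.size), labels] = 1.0
    P = (1.0 - delta) * P + delta / n_classes
    width = int(round(smear_ms / (HOP_S * 1000)))
    if width > 1:
        kernel = np.hanning(width + 2)[1:-1]
        kernel /= kernel.sum()
        P = np.apply_along_axis(lambda c: np.convolve(c, kernel, mode="same"), 0, P)
    P /= P.sum(axis=1, keepdims=True)
    return Posteriorgram(P, class_labels)


def group_triphones(pg: Posteriorgram, mapping: dict) -> Posteriorgram:
    """Sum context-dependent (triphone) columns into their monophones."""
    unmapped = [lab for lab in pg.labels if lab not in mapping]
    if unmapped:
        raise ValueError(f"unmapped classes: {unmapped[:5]}")
    targets = sorted(set(mapping[lab] for lab in pg.labels))
    out = np.zeros((pg.n_frames, len(targets)))
    t_index = {t: i for i, t in enumerate(targets)}
    for j, lab in enumerate(pg.labels):
        out[:, t_index[mapping[lab]]] += pg.probs[:, j]
    return Posteriorgram(out, targets, pg.hop_s)


def train_phoneme_classifier(
    stacked_features: np.ndarray,
    frame_labels: np.ndarray,
    inventory: PhonemeInventory,
    hidden_layout: tuple = (128,),
    seed: int = 0,
    max_iter: int = 60,
) -> "PhonemeClassifier":
    """Small feed-forward softmax network trained by cross-entropy."""
    y = np.asarray(frame_labels, dtype=int)
    present = np.unique(y)
    missing = [inventory.labels[i] for i in range(inventory.n_classes) if i not in present]
    if missing:
        raise ValueError(f"classes absent from training data: {missing}")
    clf = MLPClassifier(
        hidden_layer_sizes=hidden_layout,
        random_state=seed,
        max_iter=max_iter,
        early_stopping=True,
        n_iter_no_change=8,
    )
    clf.fit(np.asarray(stacked_features, dtype=float), y)
    return PhonemeClassifier(clf, inventory)


class PhonemeClassifier:
    """Waveform -> Posteriorgram provider wrapping the trained network.

    Applies per-utterance mean normalization of the log-mel features
    (level invariance) before context stacking.
    """

    def __init__(self, model: MLPClassifier, inventory: PhonemeInventory,
                 left: int = 5, right: int = 5, cmn: bool = True):
        self.model = model
        self.inventory = inventory
        self.left = left
        self.right = right
        self.cmn = cmn

    def features(self, waveform: np.ndarray, sample_rate: int = 16000) -> np.ndarray:
        feats = logmel(waveform, sample_rate)
        if self.cmn:
            feats = feats - feats.mean(axis=0, keepdims=True)
        return stack_context(feats, self.left, self.right)

    def posteriorgram(self, waveform: np.ndarray, sample_rate: int = 16000) -> Posteriorgram:
        X = self.features(waveform, sample_rate)
        proba = self.model.predict_proba(X)
        # column order follows model.classes_ (a subset ordering of 0..C-1)
        full = np.zeros((proba.shape[0], self.inventory.n_classes))
        full[:, self.model.classes_.astype(int)] = proba
        full /= full.sum(axis=1, keepdims=True)
        return Posteriorgram(full, list(self.inventory.labels))

    def __call__(self, waveform: np.ndarray, sample_rate: int = 16000) -> Posteriorgram:
        return self.posteriorgram(waveform, sample_rate)

    def accuracy(self, waveform: np.ndarray, frame_labels: np.ndarray,
                 sample_rate: int = 16000) -> float:
        X = self.features(waveform, sample_rate)
        return float(np.mean(self.model.predict(X) == np.asarray(frame_labels)))


def train_default_provider(
    seed: int = 0,
    train_duration_s: float = 60.0,
    sample_rate: int = 16000,
    hidden_layout: tuple = (128,),
    noisy_snrs_db: tuple = (10.0, 15.0, 20.0),
) -> PhonemeClassifier:
    """Multi-condition training on synthetic phone streams.

    Clean streams plus copies mixed with stationary speech-shaped noise at
    10-20 dB SNR (labels kept from the clean alignment), mirroring
    multi-condition acoustic-model training.
    """
    inv = PhonemeInventory()
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2 + len(noisy_snrs_db))]
    X_parts, y_parts = [], []
    wave, labels = synth_phone_stream(inv, train_duration_s, seeds[0], sample_rate)
    provider_tmp = PhonemeClassifier(None, inv)  # feature plumbing only
    X_parts.append(provider_tmp.features(wave, sample_rate))
    y_parts.append(labels)
    per_noisy = train_duration_s / max(1, len(noisy_snrs_db))
    for i, snr in enumerate(noisy_snrs_db):
        w, lab = synth_phone_stream(inv, per_noisy, seeds[1 + i], sample_rate)
        rng = np.random.default_rng(seeds[-1] + i)
        noise = speech_shaped_noise(w.size, sample_rate, rng)
        p_sig = np.mean(w[np.abs(w) > 1e-6] ** 2) if np.any(np.abs(w) > 1e-6) else np.mean(w**2)
        g = np.sqrt(p_sig / (np.mean(noise**2) * 10 ** (snr / 10)))
        X_parts.append(provider_tmp.features(w + g * noise, sample_rate))
        y_parts.append(lab)
    clf = train_phoneme_classifier(
        np.concatenate(X_parts), np.concatenate(y_parts), inv,
        hidden_layout=hidden_layout, seed=seed,
    )
    return clf
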