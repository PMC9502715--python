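"""Synthetic multichannel acoustic scenes with known ground truth.

A scene is one localized speech-like source in either a diffuse
speech-shaped noise field or a localized weakly-modulated broadband
interferer, at a prescribed SNR, in an anechoic or reverberant room.
Spatialization uses a far-field plane-wave fractional-delay model (an
importer for user-supplied multichannel impulse responses is provided via
:func:`spatialize_with_ir`); reverberation is an exponentially decaying
random tail appended to the direct path.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.io import wavfile
from scipy import signal as sps

from .core import ArrayGeometry, MultichannelSignal
from .signals import phone_stream, speech_shaped_noise

__all__ = [
    "SceneSpec",
    "synth_speechlike",
    "synth_interferer",
    "spatialize",
    "spatialize_with_ir",
    "diffuse_noise",
    "mix_at_snr",
    "noise_gain_for_snr",
    "apply_reverb",
    "reverb_tail",
    "build_scene",
    "read_wav",
    "write_wav",
]


@dataclass
class SceneSpec:
    """Declarative description of one simulated scene.

    Defaults follow the reference setup: talker at -30 deg, localized
    interferer (when used) at +40 deg, frontal-hemisphere azimuths, SNR on
    the reference channel over target-active samples.
    """

    snr_db: float
    seed: int
    target_azimuth_deg: float = -30.0
    noise_kind: str = "diffuse"  # {"diffuse", "localized"}
    interferer_azimuth_deg: float = 40.0
    room: str = "anechoic"  # {"anechoic", "reverberant"}
    t60_s: float = 0.0
    duration_s: float = 3.0

    def __post_init__(self) -> None:
        if self.noise_kind not in ("diffuse", "localized"):
            raise ValueError(f"unknown noise_kind {self.noise_kind!r}")
        if self.room not in ("anechoic", "reverberant"):
            raise ValueError(f"unknown room {self.room!r}")
        for name in ("target_azimuth_deg", "interferer_azimuth_deg"):
            a = getattr(self, name)
            if not -90.0 <= a <= 90.0:
                raise ValueError(f"{name}={a} outside the frontal hemisphere [-90, 90]")
        if not np.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.t60_s < 0:
            raise ValueError("t60_s must be non-negative")
        if self.room == "anechoic" and self.t60_s != 0:
            raise ValueError("anechoic room requires t60_s = 0")
        if self.room == "reverberant" and self.t60_s == 0:
            self.t60_s = 0.5

    def to_text(self) -> str:
        """Serialize as flat ``key: value`` lines."""
        return "\n".join(f"{k}: {v}" for k, v in asdict(self).items()) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "SceneSpec":
        kv: dict = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition(":")
            key = key.strip()
            val = val.strip()
            if key in ("noise_kind", "room"):
                kv[key] = val
            elif key == "seed":
                kv[key] = int(val)
            else:
                kv[key] = float(val)
        return cls(**kv)


def synth_speechlike(duration_s: float, sample_rate: int, seed: int) -> np.ndarray:
    """Speech-shaped test source: phone stream with syllabic amplitude modulation.

    A random sequence of harmonic/formant and noise-burst phone segments with
    silent gaps, multiplied by a 2-8 Hz envelope, giving the strong modulation
    depth characteristic of running speech.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    wave, _ = phone_stream(duration_s, sample_rate, seed, silence_prob=0.2)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA5]))
    n = wave.size
    sos = sps.butter(2, [2.0, 8.0], btype="bandpass", fs=sample_rate, output="sos")
    env = sps.sosfiltfilt(sos, rng.standard_normal(n))
    lo, hi = env.min(), env.max()
    env = (env - lo) / (hi - lo) if hi > lo else np.ones(n)
    return wave * (0.25 + 0.75 * env)


def synth_interferer(duration_s: float, sample_rate: int, seed: int) -> np.ndarray:
    """Weakly modulated broadband interferer (vacuum-cleaner-like).

    Near-white broadband noise with a low-frequency motor-hum harmonic stack
    and a shallow (~5%) amplitude ripple; spectrally much flatter and far
    less modulated than the speech-like source.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sample_rate))
    t = np.arange(n) / sample_rate
    noise = rng.standard_normal(n)
    hum = sum(
        (0.5 / k) * np.sin(2 * np.pi * 120.0 * k * t + rng.uniform(0, 2 * np.pi))
        for k in range(1, 6)
    )
    x = noise + 0.3 * hum
    x *= 1.0 + 0.05 * np.sin(2 * np.pi * 23.0 * t)
    return 0.1 * x / np.sqrt(np.mean(x**2))


def _pad_margin(geometry: ArrayGeometry) -> tuple[int, float]:
    """(padding samples, bulk delay in s) making all spatialized delays causal."""
    offset_s = float(np.linalg.norm(geometry.mic_positions, axis=1).max()) / geometry.speed_of_sound
    margin = int(np.ceil(2 * offset_s * geometry.sample_rate)) + 2
    return margin, offset_s


def spatialize(
    source: np.ndarray,
    azimuth_deg: float,
    geometry: ArrayGeometry,
    head_shadow: bool = False,
) -> MultichannelSignal:
    """Place a mono source at ``azimuth_deg`` using plane-wave fractional delays.

    Each channel is the source delayed by tau_m = -(p_m . u)/c (plus a common
    bulk delay keeping all channels causal; the output is ``margin`` samples
    longer than the input).  With ``head_shadow`` a first-order low-pass and
    broadband attenuation are applied to the side of the head facing away
    from the source.
    """
    source = np.asarray(source, dtype=float)
    if source.size == 0:
        raise ValueError("empty source signal")
    if not -180.0 <= azimuth_deg <= 180.0:
        raise ValueError("azimuth must lie in [-180, 180]")
    sr = geometry.sample_rate
    margin, offset_s = _pad_margin(geometry)
    n_out = source.size + margin
    X = np.fft.rfft(source, n=n_out)
    f = np.fft.rfftfreq(n_out, 1.0 / sr)
    taus = geometry.delays(azimuth_deg) + offset_s
    out = np.empty((geometry.n_mics, n_out))
    src_y = -np.sin(np.deg2rad(azimuth_deg))  # +1 when source is fully left
    for m, tau in enumerate(taus):
        Xm = X * np.exp(-2j * np.pi * f * tau)
        if head_shadow:
            mic_y = geometry.mic_positions[m, 1]
            shade = max(0.0, -np.sign(mic_y) * src_y)  # 1 = fully contralateral
            if shade > 0:
                fc = 8000.0 / (1.0 + 3.0 * shade)
                Xm = Xm / (1.0 + 1j * f / fc) * 10 ** (-3.0 * shade / 20.0)
        out[m] = np.fft.irfft(Xm, n=n_out)
    return MultichannelSignal(out, sr, geometry)


def spatialize_with_ir(source: np.ndarray, impulse_responses: np.ndarray,
                       geometry: ArrayGeometry) -> MultichannelSignal:
    """Spatialize with user-supplied multichannel impulse responses.

    ``impulse_responses`` is ``(M, L)`` — one measured (e.g. head-related)
    impulse response per channel for one direction.
    """
    source = np.asarray(source, dtype=float)
    if source.size == 0:
        raise ValueError("empty source signal")
    irs = np.atleast_2d(np.asarray(impulse_responses, dtype=float))
    if irs.shape[0] != geometry.n_mics:
        raise ValueError("impulse response channel count must match geometry")
    out = np.stack([sps.fftconvolve(source, h) for h in irs])
    return MultichannelSignal(out, geometry.sample_rate, geometry)


def diffuse_noise(
    duration_s: float,
    geometry: ArrayGeometry,
    n_directions: int = 19,
    seed: int = 0,
    head_shadow: bool = True,
) -> MultichannelSignal:
    """Diffuse stationary field: independent speech-shaped noises from
    ``n_directions`` equally spaced azimuths over the full circle."""
    if n_directions < 2:
        raise ValueError("n_directions must be at least 2")
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    n = int(round(duration_s * geometry.sample_rate))
    azimuths = np.linspace(-180.0, 180.0, n_directions, endpoint=False)
    children = np.random.SeedSequence(seed).spawn(n_directions)
    total = None
    for az, child in zip(azimuths, children):
        src = speech_shaped_noise(n, geometry.sample_rate, np.random.default_rng(child))
        # directions outside [-180,180] never occur here; spatialize accepts all
        sig = spatialize(src, float(az), geometry, head_shadow=head_shadow)
        total = sig.samples if total is None else total + sig.samples
    return MultichannelSignal(total / np.sqrt(n_directions), geometry.sample_rate, geometry)


def _active_mask(x: np.ndarray, sample_rate: int,
                 frame_s: float = 0.02, threshold_db: float = 40.0) -> np.ndarray:
    """Samples belonging to frames within ``threshold_db`` of the peak frame energy."""
    frame = max(1, int(frame_s * sample_rate))
    n_frames = max(1, x.size // frame)
    e = np.add.reduceat(x[: n_frames * frame] ** 2, np.arange(0, n_frames * frame, frame))
    active = e > e.max() * 10 ** (-threshold_db / 10)
    mask = np.zeros(x.size, dtype=bool)
    for i in np.flatnonzero(active):
        mask[i * frame : (i + 1) * frame] = True
    return mask


def noise_gain_for_snr(
    target: MultichannelSignal,
    noise: MultichannelSignal,
    snr_db: float,
    reference_channel: int = 0,
) -> float:
    """Scalar gain for ``noise`` so the reference-channel SNR over
    target-active samples equals ``snr_db``."""
    if target.samples.shape != noise.samples.shape:
        raise ValueError("target and noise must have equal shapes")
    if target.sample_rate != noise.sample_rate:
        raise ValueError("sample rates differ")
    t = target.samples[reference_channel]
    v = noise.samples[reference_channel]
    mask = _active_mask(t, target.sample_rate)
    p_t = np.mean(t[mask] ** 2)
    p_n = np.mean(v[mask] ** 2)
    if p_n <= 0 or p_t <= 0:
        raise ValueError("cannot scale: silent noise or silent target")
    return float(np.sqrt(p_t / (p_n * 10 ** (snr_db / 10))))


def mix_at_snr(
    target: MultichannelSignal,
    noise: MultichannelSignal,
    snr_db: float,
    reference_channel: int = 0,
) -> MultichannelSignal:
    """Sum of target and scaled noise achieving ``snr_db`` (within 0.01 dB)
    on the reference channel over target-active samples."""
    g = noise_gain_for_snr(target, noise, snr_db, reference_channel)
    return MultichannelSignal(
        target.samples + g * noise.samples, target.sample_rate, target.geometry
    )


def reverb_tail(t60_s: float, sample_rate: int, seed: int) -> np.ndarray:
    """Random-phase exponentially decaying tail whose Schroeder energy decay
    reaches -60 dB at ``t60_s`` (unit total energy)."""
    if t60_s <= 0:
        raise ValueError("t60_s must be positive for a tail")
    n = int(round(1.2 * t60_s * sample_rate))
    t = np.arange(n) / sample_rate
    rng = np.random.default_rng(seed)
    tail = rng.standard_normal(n) * 10 ** (-3.0 * t / t60_s)
    return tail / np.sqrt(np.sum(tail**2))


def apply_reverb(
    signal: MultichannelSignal,
    t60_s: float,
    seed: int,
    tail_start_s: float = 0.005,
    direct_to_reverb_db: float = 3.0,
) -> MultichannelSignal:
    """Per-channel convolution with direct path + decaying random tail.

    ``t60_s = 0`` is the identity.  Tails are drawn independently per
    channel (decorrelated late reverberation); the tail energy is set
    ``direct_to_reverb_db`` below the direct path.
    """
    if t60_s < 0:
        raise ValueError("t60_s must be non-negative")
    if t60_s == 0:
        return MultichannelSignal(
            signal.samples.copy(), signal.sample_rate, signal.geometry
        )
    sr = signal.sample_rate
    start = int(round(tail_start_s * sr))
    tail_gain = 10 ** (-direct_to_reverb_db / 20)
    children = np.random.SeedSequence(seed).spawn(signal.n_channels)
    out = np.empty_like(signal.samples)
    for c in range(signal.n_channels):
        tail = reverb_tail(t60_s, sr, children[c]) * tail_gain
        h = np.zeros(start + tail.size)
        h[0] = 1.0
        h[start:] = tail
        out[c] = sps.fftconvolve(signal.samples[c], h)[: signal.n_samples]
    return MultichannelSignal(out, sr, signal.geometry)


def build_scene(
    spec: SceneSpec, geometry: ArrayGeometry, head_shadow: bool = True
) -> tuple[MultichannelSignal, dict]:
    """Compose one scene per its spec; returns (signal, ground-truth record).

    ``head_shadow`` (default on) applies the contralateral first-order
    low-pass during spatialization, providing the interaural level/phase
    asymmetry that measured head-related impulse responses would supply.
    """
    sr = geometry.sample_rate
    ss = np.random.SeedSequence(spec.seed)
    seed_target, seed_noise, seed_rev_t, seed_rev_n = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)
    )
    target = synth_speechlike(spec.duration_s, sr, seed_target)
    target_mc = spatialize(target, spec.target_azimuth_deg, geometry, head_shadow)
    if spec.noise_kind == "diffuse":
        noise_mc = diffuse_noise(spec.duration_s, geometry, 19, seed_noise, head_shadow)
    else:
        interferer = synth_interferer(spec.duration_s, sr, seed_noise)
        noise_mc = spatialize(interferer, spec.interferer_azimuth_deg, geometry, head_shadow)
    if spec.room == "reverberant":
        target_mc = apply_reverb(target_mc, spec.t60_s, seed_rev_t)
        noise_mc = apply_reverb(noise_mc, spec.t60_s, seed_rev_n)
    mixed = mix_at_snr(target_mc, noise_mc, spec.snr_db)
    truth = {
        "target_sector": spec.target_azimuth_deg,
        "interferer_sector": (
            spec.interferer_azimuth_deg if spec.noise_kind == "localized" else None
        ),
        "snr_db": spec.snr_db,
        "noise_kind": spec.noise_kind,
        "room": spec.room,
        "seed": spec.seed,
    }
    return mixed, truth


def write_wav(path, samples: np.ndarray, sample_rate: int, subtype: str = "float32") -> None:
    """Write mono or multichannel audio ((C, N) or (N,)) as WAV.

    ``subtype``: "float32" or "pcm16" (scipy cannot write 24-bit PCM;
    24-bit files are supported on read).
    """
    x = np.asarray(samples)
    if x.ndim == 2:
        x = x.T  # scipy expects (N, C)
    if subtype == "float32":
        wavfile.write(path, sample_rate, x.astype(np.float32))
    elif subtype == "pcm16":
        peak = np.abs(x).max()
        if peak > 1.0:
            x = x / peak
        wavfile.write(path, sample_rate, (x * 32767).astype(np.int16))
    else:
        raise ValueError(f"unsupported subtype {subtype!r}")


def read_wav(path) -> tuple[np.ndarray, int]:
    """Read a WAV file as ((C, N) float in [-1, 1], sample_rate)."""
    sr, data = wavfile.read(path)
    if data.dtype == np.int16:
        x = data / 32768.0
    elif data.dtype == np.int32:
        x = data / 2147483648.0
    elif data.dtype == np.uint8:
        x = (data.astype(float) - 128.0) / 128.0
    else:
        x = data.astype(float)
    if x.ndim == 2:
        x = x.T
    else:
        x = x[None, :]
    return x, sr
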