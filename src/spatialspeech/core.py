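"""Shared domain types: array geometry, multichannel audio, direction profiles.

Coordinate convention: x points to the front of the listener, y to the left,
z up; azimuth is measured in degrees from the front, negative to the left
(a talker at -30 deg is front-left).  A far-field plane wave from azimuth
``a`` propagates along ``-u(a)`` with ``u(a) = (cos a, -sin a, 0)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ArrayGeometry",
    "MultichannelSignal",
    "DirectionProfile",
    "default_bte_array",
    "DEFAULT_AZIMUTH_GRID",
    "azimuth_unit_vector",
]

#: 19 steering/evaluation sectors spanning the frontal hemisphere, 10 deg wide.
DEFAULT_AZIMUTH_GRID = np.arange(-90.0, 91.0, 10.0)


def azimuth_unit_vector(azimuth_deg: float) -> np.ndarray:
    """Unit vector pointing from the head centre toward azimuth ``azimuth_deg``."""
    a = np.deg2rad(azimuth_deg)
    return np.array([np.cos(a), -np.sin(a), 0.0])


@dataclass(frozen=True)
class ArrayGeometry:
    """Microphone array layout.

    Parameters
    ----------
    mic_positions
        ``(M, 3)`` coordinates in metres relative to the head centre.
    sample_rate
        Sampling rate in Hz.
    speed_of_sound
        Propagation speed in m/s (default 343).
    """

    mic_positions: np.ndarray
    sample_rate: int
    speed_of_sound: float = 343.0

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.mic_positions, dtype=float))
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("mic_positions must be an (M, 3) array of metres")
        if pos.shape[0] < 2:
            raise ValueError("an array needs at least 2 microphones")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.speed_of_sound <= 0:
            raise ValueError("speed_of_sound must be positive")
        object.__setattr__(self, "mic_positions", pos)
        if self.aperture <= 0:
            raise ValueError("array aperture must be positive (coincident mics?)")

    @property
    def n_mics(self) -> int:
        return self.mic_positions.shape[0]

    @property
    def aperture(self) -> float:
        """Largest pairwise microphone distance in metres."""
        diff = self.mic_positions[:, None, :] - self.mic_positions[None, :, :]
        return float(np.sqrt((diff**2).sum(-1)).max())

    def delays(self, azimuth_deg: float) -> np.ndarray:
        """Per-microphone plane-wave arrival delays in seconds.

        tau_m(a) = -(p_m . u(a)) / c; a microphone closer to the source
        (larger projection on u) receives the wavefront earlier.
        """
        u = azimuth_unit_vector(azimuth_deg)
        return -(self.mic_positions @ u) / self.speed_of_sound

    def max_delay_samples(self) -> int:
        """Upper bound on inter-mic delay in samples, plus a 2-sample guard."""
        return int(np.ceil(self.aperture / self.speed_of_sound * self.sample_rate)) + 2


def default_bte_array(sample_rate: int = 16000) -> ArrayGeometry:
    """Six-mic behind-the-ear layout: two lateral triplets at +/-9 cm.

    Channel order: front-left, mid-left, rear-left, front-right, mid-right,
    rear-right.  Within a triplet the mics are 1.5 cm apart along the
    front-back axis, typical of a BTE hearing-aid shell.
    """
    dx = 0.015
    left = [[dx, 0.09, 0.0], [0.0, 0.09, 0.0], [-dx, 0.09, 0.0]]
    right = [[dx, -0.09, 0.0], [0.0, -0.09, 0.0], [-dx, -0.09, 0.0]]
    return ArrayGeometry(np.array(left + right), sample_rate)


#: channel subset used for DOA feature extraction: front+rear of each triplet.
FRONT_REAR_SUBSET = (0, 2, 3, 5)


@dataclass
class MultichannelSignal:
    """Sampled multichannel audio with its array geometry.

    ``samples`` is a ``(channels, time)`` float array.
    """

    samples: np.ndarray
    sample_rate: int
    geometry: ArrayGeometry

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("signal contains non-finite samples")
        if self.samples.shape[0] != self.geometry.n_mics:
            raise ValueError(
                f"channel count {self.samples.shape[0]} does not match "
                f"geometry mic count {self.geometry.n_mics}"
            )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate


@dataclass
class DirectionProfile:
    """One scalar per steering azimuth — the currency of the fusion stage.

    ``kind`` tags the semantics: "ASQM" (raw quality profile), "P_DOA"
    (time-averaged source probability), "P_ASQM" (rescaled quality), or
    "P_s" (fused joint likelihood).  Probability-tagged profiles must lie
    in [0, 1].
    """

    values: np.ndarray
    azimuth_grid: np.ndarray
    kind: str = "ASQM"
    degenerate: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.azimuth_grid = np.asarray(self.azimuth_grid, dtype=float)
        if self.values.shape != self.azimuth_grid.shape:
            raise ValueError("values and azimuth_grid must have equal length")
        if self.values.size == 0:
            raise ValueError("empty direction profile")
        if np.any(np.diff(self.azimuth_grid) <= 0):
            raise ValueError("azimuth_grid must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("profile contains non-finite values")
        if self.kind.startswith("P_") and (
            self.values.min() < -1e-9 or self.values.max() > 1 + 1e-9
        ):
            raise ValueError(f"{self.kind} profile must lie in [0, 1]")

    def __len__(self) -> int:
        return self.values.size
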