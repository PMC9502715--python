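"""Single-ended speech quality measures on phoneme posteriorgrams.

Three measures, each mapping one posteriorgram to one scalar:

* **M-Measure (MM)** — mean divergence between posterior vectors separated
  by a lag ``dt``, averaged over time and over a lag grid (50-800 ms).
  Temporal smearing of activations lowers it.
* **MaP filtering** — each phone's activation trace is convolved with a
  matched filter learned from clean data; above-threshold peaks count as
  phonetic events.  Degraded speech produces fewer events.
* **Inverse entropy (iEnt)** — negated average frame-wise entropy; sparse
  (confident) posteriorgrams score high.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .core import DirectionProfile
from .posteriorgram import Posteriorgram

__all__ = [
    "MMConfig",
    "MatchedFilterSet",
    "AsqmResult",
    "m_measure",
    "learn_map_filters",
    "map_events",
    "inverse_entropy",
    "asqm_profile",
    "MEASURES",
]

EPSILON = 1e-10


@dataclass
class MMConfig:
    """M-Measure configuration.

    ``delta_grid_ms`` defaults to the saturated part of the divergence
    curve, 50-800 ms in 50 ms steps.  ``divergence`` selects plain forward
    KL or its symmetrised mean.
    """

    delta_grid_ms: tuple = tuple(range(50, 801, 50))
    epsilon: float = EPSILON
    divergence: str = "symmetric_kl"

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.delta_grid_ms):
            raise ValueError("all delta_t values must be positive")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.divergence not in ("kl", "symmetric_kl"):
            raise ValueError(f"unknown divergence {self.divergence!r}")


@dataclass
class MatchedFilterSet:
    """Per-phone matched filters (time-reversed mean clean activation traces),
    normalized so a perfect clean match peaks at 1.0."""

    filters: dict  # label -> taps (support_frames,)
    support_frames: int
    labels: list[str]

    def __post_init__(self) -> None:
        missing = [lab for lab in self.labels if lab not in self.filters]
        if missing:
            raise ValueError(f"filters missing for classes: {missing}")

    def save(self, path) -> None:
        taps = np.stack([self.filters[lab] for lab in self.labels])
        np.savez(path, taps=taps, labels=np.array(self.labels),
                 support=self.support_frames)

    @classmethod
    def load(cls, path) -> "MatchedFilterSet":
        z = np.load(path, allow_pickle=False)
        labels = [str(l) for l in z["labels"]]
        taps = z["taps"]
        return cls({lab: taps[i] for i, lab in enumerate(labels)},
                   int(z["support"]), labels)


@dataclass
class AsqmResult:
    """Scalar quality value plus per-measure diagnostics."""

    measure: str
    value: float
    diagnostics: dict = field(default_factory=dict)


def _floored(P: np.ndarray, eps: float) -> np.ndarray:
    Q = np.maximum(P, eps)
    return Q / Q.sum(axis=1, keepdims=True)


def _kl_rows(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Row-wise KL(P||Q) in bits."""
    return np.sum(P * np.log2(P / Q), axis=1)


def m_measure(pg: Posteriorgram, config: MMConfig | None = None) -> AsqmResult:
    """Mean temporal distance:

        M(dt) = 1/(T-dt) * sum_{t=dt}^{T} D(P(t-dt), P(t)),

    averaged uniformly over the feasible lag grid.  Lags exceeding the
    utterance are dropped (flagged in diagnostics); no lag feasible is an
    error.
    """
    config = config or MMConfig()
    P = _floored(pg.probs, config.epsilon)
    T = P.shape[0]
    hop_ms = pg.hop_s * 1000.0
    curve = {}
    skipped = []
    for dt_ms in config.delta_grid_ms:
        lag = int(round(dt_ms / hop_ms))
        if lag < 1 or lag >= T:
            skipped.append(dt_ms)
            continue
        A, B = P[:-lag], P[lag:]
        if config.divergence == "kl":
            d = _kl_rows(A, B)
        else:
            d = 0.5 * (_kl_rows(A, B) + _kl_rows(B, A))
        curve[dt_ms] = float(d.mean())
    if not curve:
        raise ValueError(
            f"posteriorgram ({T} frames) shorter than the smallest lag "
            f"{min(config.delta_grid_ms)} ms"
        )
    value = float(np.mean(list(curve.values())))
    return AsqmResult("MM", value, {"per_delta": curve, "skipped_delta_ms": skipped})


def learn_map_filters(
    posteriorgrams: list[Posteriorgram],
    frame_labels: list[np.ndarray],
    support_frames: int = 51,
) -> MatchedFilterSet:
    """Learn matched filters from clean labelled posteriorgrams.

    For each class, activation traces of its occurrences (contiguous label
    runs) are collected in windows of ``support_frames`` centred on the run
    midpoints and averaged; the filter is the time-reversed average,
    normalized so convolving it with the average trace peaks at 1.0.
    """
    if support_frames < 1:
        raise ValueError("support_frames must be positive")
    labels_list = [np.asarray(l, dtype=int) for l in frame_labels]
    n_classes = len(posteriorgrams[0].labels)
    class_labels = list(posteriorgrams[0].labels)
    half = support_frames // 2
    traces: dict[int, list] = {c: [] for c in range(n_classes)}
    for pg, labs in zip(posteriorgrams, labels_list):
        if labs.size != pg.n_frames:
            raise ValueError("labels not aligned to posteriorgram frames")
        change = np.flatnonzero(np.diff(labs)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [labs.size]])
        for s, e in zip(starts, ends):
            c = labs[s]
            mid = (s + e - 1) // 2
            window = np.zeros(support_frames)
            lo = max(0, mid - half)
            hi = min(labs.size, mid - half + support_frames)
            window[lo - (mid - half) : hi - (mid - half)] = pg.probs[lo:hi, c]
            traces[c].append(window)
    missing = [class_labels[c] for c in range(n_classes) if not traces[c]]
    if missing:
        raise ValueError(f"no occurrences for classes: {missing}")
    filters = {}
    for c in range(n_classes):
        avg = np.mean(traces[c], axis=0)
        h = avg[::-1].copy()
        peak = np.convolve(avg, h).max()
        if peak <= 0:
            raise ValueError(f"degenerate filter for class {class_labels[c]}")
        filters[class_labels[c]] = h / peak
    return MatchedFilterSet(filters, support_frames, class_labels)


def map_events(
    pg: Posteriorgram, filters: MatchedFilterSet, threshold: float = 0.5
) -> AsqmResult:
    """Count phonetic events: per class, local maxima of the matched-filter
    output strictly above ``threshold``, separated by at least half the
    filter support."""
    missing = [lab for lab in pg.labels if lab not in filters.filters]
    if missing:
        raise ValueError(f"filter set does not cover classes: {missing}")
    min_sep = max(1, filters.support_frames // 2)
    counts = {}
    for j, lab in enumerate(pg.labels):
        y = np.convolve(pg.probs[:, j], filters.filters[lab], mode="same")
        peaks, _ = find_peaks(y, distance=min_sep)
        counts[lab] = int(np.sum(y[peaks] > threshold))
    total = sum(counts.values())
    return AsqmResult("MaP", float(total), {"per_class_events": counts})


def inverse_entropy(pg: Posteriorgram, mode: str = "negative") -> AsqmResult:
    """Average frame-wise entropy H (bits), returned inverted.

    ``mode='negative'`` gives -H; ``'reciprocal'`` gives 1/(H + eps).  Both
    are strictly decreasing in H, so any downstream argmax is identical.
    """
    P = pg.probs  # row-normalization validated by the Posteriorgram type
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(P > 0, -P * np.log2(np.where(P > 0, P, 1.0)), 0.0)
    H = float(terms.sum(axis=1).mean())
    if mode == "negative":
        value = -H
    elif mode == "reciprocal":
        value = 1.0 / (H + EPSILON)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return AsqmResult("iEnt", value, {"mean_entropy_bits": H,
                                      "per_frame_entropy": terms.sum(axis=1)})


def _measure_value(pg: Posteriorgram, measure: str, *,
                   mm_config: MMConfig | None = None,
                   filters: MatchedFilterSet | None = None) -> float:
    if measure == "MM":
        return m_measure(pg, mm_config).value
    if measure == "MaP":
        if filters is None:
            raise ValueError("MaP requires a MatchedFilterSet")
        return map_events(pg, filters).value
    if measure == "iEnt":
        return inverse_entropy(pg).value
    raise ValueError(f"unknown measure {measure!r}")


MEASURES = ("MM", "MaP", "iEnt")


def asqm_profile(
    sector_signals: np.ndarray,
    azimuth_grid: np.ndarray,
    provider,
    measure: str = "MM",
    sample_rate: int = 16000,
    mm_config: MMConfig | None = None,
    filters: MatchedFilterSet | None = None,
) -> DirectionProfile:
    """ASQM(alpha): one quality scalar per beamformed steering direction.

    ``provider`` maps (waveform, sample_rate) -> Posteriorgram, e.g. a
    trained :class:`~spatialspeech.posteriorgram.PhonemeClassifier`.
    """
    sector_signals = np.atleast_2d(sector_signals)
    if sector_signals.shape[0] < 2:
        raise ValueError("need at least 2 sectors")
    values = np.empty(sector_signals.shape[0])
    for i, wave in enumerate(sector_signals):
        try:
            pg = provider(wave, sample_rate)
            values[i] = _measure_value(pg, measure, mm_config=mm_config, filters=filters)
        except Exception as exc:
            raise RuntimeError(
                f"posteriorgram/measure failure at sector {azimuth_grid[i]} deg: {exc}"
            ) from exc
    return DirectionProfile(values, np.asarray(azimuth_grid, dtype=float),
                            kind="ASQM", meta={"measure": measure})
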