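"""Fusion of DOA probability and speech-quality profiles, localization
estimators, and hit-rate scoring.

The quality profile is rescaled per utterance to [0, 1] and multiplied with
the time-averaged DOA probability, giving the joint spatial speech
likelihood P_s(alpha).  Localization is the argmax of either P_s, P_DOA or
P_ASQM; a hit means the estimate falls in the true source's 10-degree
sector (equivalently a +/-5 degree tolerance).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .asqm import MEASURES, MMConfig, MatchedFilterSet, asqm_profile
from .beamform import BeamformerBank, beamform_all
from .core import DirectionProfile, MultichannelSignal
from .doa import DoaModel, average_map, probability_map

__all__ = [
    "EvalRecord",
    "Estimate",
    "rescale_asqm",
    "fuse",
    "estimate_direction",
    "hit_rate",
    "evaluate_scene",
    "evaluate_methods",
]


class Estimate(NamedTuple):
    azimuth_deg: float
    tie: bool


@dataclass
class EvalRecord:
    """Per-scene evaluation outcome: truth, per-method estimates, hits."""

    true_sector: float
    estimates: dict  # method name -> estimated azimuth
    interferer_sector: float | None = None
    meta: dict = field(default_factory=dict)

    def hit(self, method: str) -> int:
        return int(self.estimates[method] == self.true_sector)

    def interferer_selected(self, method: str) -> int | None:
        if self.interferer_sector is None:
            return None
        return int(self.estimates[method] == self.interferer_sector)


def rescale_asqm(profile: DirectionProfile) -> DirectionProfile:
    """Min-max rescale per utterance: P_ASQM = (x - min) / (max - min).

    A constant profile carries no directional information; it maps to
    all-ones (degenerate flag set) so the fusion falls back to P_DOA.
    """
    if len(profile) < 2:
        raise ValueError("need at least 2 sectors to rescale")
    x = profile.values
    span = x.max() - x.min()
    if span == 0:
        return DirectionProfile(np.ones_like(x), profile.azimuth_grid,
                                kind="P_ASQM", degenerate=True, meta=dict(profile.meta))
    return DirectionProfile((x - x.min()) / span, profile.azimuth_grid,
                            kind="P_ASQM", meta=dict(profile.meta))


def fuse(p_asqm: DirectionProfile, p_doa: DirectionProfile) -> DirectionProfile:
    """Joint spatial speech likelihood: P_s(alpha) = P_ASQM(alpha) * P_DOA(alpha)."""
    if not np.array_equal(p_asqm.azimuth_grid, p_doa.azimuth_grid):
        raise ValueError("azimuth grids do not match")
    return DirectionProfile(p_asqm.values * p_doa.values, p_doa.azimuth_grid,
                            kind="P_s", meta={**p_asqm.meta, **p_doa.meta})


def estimate_direction(profile: DirectionProfile) -> Estimate:
    """Argmax over sectors; ties resolve to the lowest azimuth (flagged)."""
    x = profile.values
    if np.any(np.isnan(x)):
        raise ValueError("profile contains NaN")
    best = int(np.argmax(x))  # argmax returns the first (lowest-azimuth) maximizer
    tie = bool(np.sum(x == x[best]) > 1)
    return Estimate(float(profile.azimuth_grid[best]), tie)


def hit_rate(records: list[EvalRecord], method: str,
             azimuth_grid: np.ndarray | None = None) -> float:
    """Percentage of records whose estimate equals the true source sector."""
    if not records:
        raise ValueError("need at least one record")
    if azimuth_grid is not None:
        for r in records:
            if not np.any(np.isclose(azimuth_grid, r.true_sector)):
                raise ValueError(f"true sector {r.true_sector} not on the grid")
    return 100.0 * np.mean([r.hit(method) for r in records])


def interferer_rate(records: list[EvalRecord], method: str) -> float:
    """Percentage of localized-noise records whose estimate picked the interferer."""
    vals = [r.interferer_selected(method) for r in records
            if r.interferer_sector is not None]
    if not vals:
        raise ValueError("no localized-interferer records")
    return 100.0 * float(np.mean(vals))


def evaluate_scene(
    signal: MultichannelSignal,
    truth: dict,
    doa_model: DoaModel,
    bank: BeamformerBank,
    provider,
    measures: tuple = MEASURES,
    mm_config: MMConfig | None = None,
    filters: MatchedFilterSet | None = None,
) -> EvalRecord:
    """Run both processing paths on one scene and form all estimators.

    Produces estimates for "DOA" (argmax P_DOA), "ASQM:<m>" (argmax P_ASQM)
    and "DOAx<m>" (argmax P_s) for each requested measure.
    """
    p_doa = average_map(probability_map(signal, doa_model))
    sector_signals = beamform_all(signal, bank)
    estimates = {}
    est = estimate_direction(p_doa)
    estimates["DOA"] = est.azimuth_deg
    for m in measures:
        prof = asqm_profile(sector_signals, bank.azimuth_grid, provider, m,
                            signal.sample_rate, mm_config=mm_config, filters=filters)
        p_asqm = rescale_asqm(prof)
        p_s = fuse(p_asqm, p_doa)
        estimates[f"ASQM:{m}"] = estimate_direction(p_asqm).azimuth_deg
        estimates[f"DOAx{m}"] = estimate_direction(p_s).azimuth_deg
    return EvalRecord(
        true_sector=truth["target_sector"],
        estimates=estimates,
        interferer_sector=truth.get("interferer_sector"),
        meta={k: truth[k] for k in ("snr_db", "noise_kind", "room", "seed") if k in truth},
    )


def evaluate_methods(records: list[EvalRecord],
                     measures: tuple = MEASURES) -> pd.DataFrame:
    """Summarize records into a hit-rate table.

    Rows = (room, noise_kind, snr_db); columns = DOA, per-measure ASQM and
    DOAxASQM hit rates, plus the interferer-selection rate per method for
    localized-noise conditions.
    """
    if not records:
        raise ValueError("no records to summarize")
    methods = ["DOA"] + [f"ASQM:{m}" for m in measures] + [f"DOAx{m}" for m in measures]
    rows = []
    keyed: dict = {}
    for r in records:
        key = (r.meta.get("room"), r.meta.get("noise_kind"), r.meta.get("snr_db"))
        keyed.setdefault(key, []).append(r)
    for (room, kind, snr), group in sorted(keyed.items(), key=lambda kv: str(kv[0])):
        row = {"room": room, "noise_kind": kind, "snr_db": snr, "n": len(group)}
        for meth in methods:
            row[meth] = hit_rate(group, meth)
        if kind == "localized":
            for meth in methods:
                row[f"interferer%:{meth}"] = interferer_rate(group, meth)
        rows.append(row)
    return pd.DataFrame(rows)


def records_to_long(records: list[EvalRecord]) -> pd.DataFrame:
    """Per-scene long-format table (one row per scene and method)."""
    rows = []
    for i, r in enumerate(records):
        for meth, est in r.estimates.items():
            rows.append({
                "scene": i, "method": meth, "estimate_deg": est,
                "true_deg": r.true_sector, "hit": r.hit(meth),
                **r.meta,
            })
    return pd.DataFrame(rows)
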