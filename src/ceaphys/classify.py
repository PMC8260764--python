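"""Functional classification of units from z-scored pip responses.

A unit is called responsive when its z-scored response reaches
significance (|z| >= 1.96 by default, no multiple-bin correction) in at
least one bin of the 0-250 ms post-pip window of the reference epoch —
the first 4-CS block of extinction day 1, when the conditioned response
is expressed.  The sign of the extreme bin gives the functional name:
excited CEl units are CElon, inhibited ones CEloff, and responsive CEm
units are simply CEm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .psth import PSTHMatrix, ZScoredPSTH, zscore_block

__all__ = [
    "ClassificationParams",
    "UnitClassification",
    "classify_unit",
    "epoch_zscores",
    "responsive_proportion",
    "functional_name",
    "classification_table",
]


@dataclass(frozen=True)
class ClassificationParams:
    response_window: tuple[float, float] = (0.0, 0.25)  # s after pip onset
    z_threshold: float = 1.96
    criterion: str = "any_bin"      # or "max_abs": test only the extreme bin
    zscore_scale: str = "sem"       # calibrated scale for significance

    def __post_init__(self) -> None:
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be positive")
        if self.criterion not in ("any_bin", "max_abs"):
            raise ValueError("criterion must be 'any_bin' or 'max_abs'")


@dataclass(frozen=True)
class UnitClassification:
    unit_id: str
    region: str
    label: str                      # on | off | nonresponsive | unclassifiable
    peak_z: float
    peak_latency: float             # s, bin start of the extreme bin
    epoch_summaries: dict = field(default_factory=dict)

    @property
    def functional_class(self) -> str:
        return functional_name(self.region, self.label)


def functional_name(region: str, label: str) -> str:
    """Map region x response sign to the field's class names."""
    if label in ("nonresponsive", "unclassifiable"):
        return label
    if region == "CEm":
        return "CEm"
    return "CElon" if label == "on" else "CEloff"


def _response_bins(zpsth: ZScoredPSTH, window) -> np.ndarray:
    starts = zpsth.bin_starts
    width = starts[1] - starts[0] if len(starts) > 1 else 0.05
    return np.flatnonzero((starts >= window[0] - 1e-9)
                          & (starts + width <= window[1] + 1e-9))


def classify_unit(zpsth: ZScoredPSTH, region: str,
                  params: ClassificationParams = ClassificationParams(),
                  unit_id: str | None = None) -> UnitClassification:
    """Label a unit from its reference-epoch z-scored PSTH.

    Ties between equal-magnitude positive and negative extremes break
    toward the earlier bin.  An invalid baseline propagates as
    ``unclassifiable``.
    """
    unit_id = zpsth.unit_id if unit_id is None else unit_id
    if not zpsth.valid:
        return UnitClassification(unit_id, region, "unclassifiable",
                                  math.nan, math.nan)
    bins = _response_bins(zpsth, params.response_window)
    if bins.size == 0:
        raise ValueError("no bins fall inside the response window")
    zwin = zpsth.z[bins]
    peak_idx = int(np.argmax(np.abs(zwin)))  # argmax takes the earliest tie
    peak_z = float(zwin[peak_idx])
    peak_latency = float(zpsth.bin_starts[bins[peak_idx]])
    if params.criterion == "any_bin":
        responsive = bool(np.any(np.abs(zwin) >= params.z_threshold))
    else:
        responsive = abs(peak_z) >= params.z_threshold
    if not responsive:
        return UnitClassification(unit_id, region, "nonresponsive",
                                  peak_z, peak_latency)
    label = "on" if peak_z > 0 else "off"
    return UnitClassification(unit_id, region, label, peak_z, peak_latency)


def epoch_zscores(psth: PSTHMatrix, epochs: dict,
                  response_window=(0.0, 0.25), scale: str = "sd",
                  ) -> dict[str, float]:
    """Mean response-window z per named epoch.

    ``epochs`` maps an epoch name to the trial indices of its block
    (e.g. habituation block, first extinction block, last extinction
    block); this is the per-epoch statistic summarized in population
    figures.
    """
    out = {}
    for name, trials in epochs.items():
        zp = zscore_block(psth, trials, scale=scale)
        if not zp.valid:
            out[name] = math.nan
            continue
        bins = _response_bins(zp, response_window)
        out[name] = float(zp.z[bins].mean())
    return out


def responsive_proportion(n_responsive: int, n_total: int) -> int:
    """Percentage of responsive units, rounded half-up to an integer."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_responsive <= n_total:
        raise ValueError("need 0 <= n_responsive <= n_total")
    return int(math.floor(100.0 * n_responsive / n_total + 0.5))


def classification_table(classifications: list[UnitClassification],
                         ) -> pd.DataFrame:
    """Export table: one row per unit plus one column per epoch summary."""
    epochs = sorted({k for c in classifications for k in c.epoch_summaries})
    rows = []
    for c in classifications:
        row = {
            "unit_id": c.unit_id,
            "region": c.region,
            "label": c.label,
            "functional_class": c.functional_class,
            "peak_z": c.peak_z,
            "peak_latency_s": c.peak_latency,
        }
        for e in epochs:
            row[f"z_{e}"] = c.epoch_summaries.get(e, math.nan)
        rows.append(row)
    return pd.DataFrame(rows)
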