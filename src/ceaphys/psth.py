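"""Pip-aligned peri-stimulus time histograms and z-score normalization.

Cue responses are quantified per sound pip: spike counts in 50-ms bins
over a window from 500 ms before to 500 ms after each pip onset, with
every pip of a CS block treated as one trial (a 4-CS block of the
standard protocol contributes 108 trials).  Responses are normalized by
the pre-pip baseline: the mean and sample standard deviation of the
single-trial counts in the ten baseline bins (-500..0 ms), pooled over
the block's trials.

Two z-score scales are provided.  ``scale="sd"`` standardizes by the
single-trial baseline standard deviation, the raw form of the transform
(and the only form when a block holds a single trial).  ``scale="sem"``
standardizes the *block-averaged* bin counts by the exact standard error
of the difference between a bin's block mean and the baseline mean,
``sd * sqrt(1/n + 1/(n*n_baseline_bins))``; under a stationary unit this
statistic is standard normal whatever the trial count, which is the
property the significance-based classifier relies on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import SpikeTrain

__all__ = [
    "PSTHMatrix",
    "ZScoredPSTH",
    "PopulationPSTH",
    "pip_psth",
    "zscore_block",
    "population_psth",
]

DEFAULT_WINDOW = (-0.5, 0.5)
DEFAULT_BIN_WIDTH = 0.05


@dataclass(frozen=True)
class PSTHMatrix:
    """Trial x bin spike counts aligned to pip onsets (half-open bins)."""

    unit_id: str
    counts: np.ndarray          # (n_trials, n_bins) integers
    bin_width: float
    window: tuple[float, float]
    onsets: np.ndarray          # pip onset per trial, seconds

    def __post_init__(self) -> None:
        counts = np.atleast_2d(np.asarray(self.counts, dtype=int))
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "onsets", np.asarray(self.onsets, dtype=float))
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if not (self.window[0] < 0 < self.window[1]):
            raise ValueError("window must straddle the pip onset")

    @property
    def n_trials(self) -> int:
        return int(self.counts.shape[0])

    @property
    def bin_starts(self) -> np.ndarray:
        return self.window[0] + self.bin_width * np.arange(self.counts.shape[1])

    @property
    def baseline_bins(self) -> np.ndarray:
        """Indices of bins lying wholly before the pip onset."""
        starts = self.bin_starts
        return np.flatnonzero(starts + self.bin_width <= 1e-9)

    def to_frame(self) -> pd.DataFrame:
        trials, bins = np.nonzero(np.ones_like(self.counts))
        return pd.DataFrame({
            "trial": trials,
            "bin_start_s": self.bin_starts[bins],
            "count": self.counts[trials, bins],
        })


@dataclass(frozen=True)
class ZScoredPSTH:
    """Per-bin z of one CS block; invalid when the baseline is silent."""

    unit_id: str
    bin_starts: np.ndarray
    z: np.ndarray
    baseline_mean: float    # counts per bin per trial
    baseline_sd: float
    n_trials: int
    scale: str = "sd"

    @property
    def valid(self) -> bool:
        return self.baseline_sd > 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_start_s": self.bin_starts, "z": self.z})


@dataclass(frozen=True)
class PopulationPSTH:
    bin_starts: np.ndarray
    mean_z: np.ndarray
    sem: np.ndarray
    n_units: int

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError("population requires at least one unit")
        if np.any(self.sem < 0):
            raise ValueError("SEM must be non-negative")


def pip_psth(spikes: SpikeTrain, onsets, window=DEFAULT_WINDOW,
             bin_width: float = DEFAULT_BIN_WIDTH) -> PSTHMatrix:
    """Bin spike counts around each pip onset (one trial per pip)."""
    onsets = np.asarray(onsets, dtype=float)
    if onsets.size == 0:
        raise ValueError("need at least one pip onset")
    if np.any(np.diff(onsets) < 0):
        raise ValueError("onsets must be sorted")
    span = window[1] - window[0]
    n_bins = round(span / bin_width)
    if abs(n_bins * bin_width - span) > 1e-9:
        raise ValueError("bin_width must divide the window length")
    edges = window[0] + bin_width * np.arange(n_bins + 1)
    abs_edges = onsets[:, None] + edges[None, :]
    idx = np.searchsorted(spikes.spike_times, abs_edges, side="left")
    counts = np.diff(idx, axis=1)
    return PSTHMatrix(spikes.unit_id, counts, bin_width, tuple(window), onsets)


def zscore_block(psth: PSTHMatrix, trials=None, scale: str = "sd",
                 ) -> ZScoredPSTH:
    """Z-score a block of trials against its pooled pre-pip baseline.

    ``trials`` selects the block (default: all trials).  A silent or
    constant baseline yields an invalid result (z = NaN) rather than a
    fabricated score; callers must check ``.valid``.
    """
    if scale not in ("sd", "sem"):
        raise ValueError("scale must be 'sd' or 'sem'")
    trials = np.arange(psth.n_trials) if trials is None else np.asarray(trials)
    if trials.size == 0:
        raise ValueError("block must contain at least one trial")
    block = psth.counts[trials]
    base_bins = psth.baseline_bins
    if base_bins.size == 0:
        raise ValueError("window contains no baseline bins")
    baseline = block[:, base_bins].ravel()
    bm = float(baseline.mean())
    bs = float(baseline.std(ddof=1)) if baseline.size > 1 else 0.0
    mean_counts = block.mean(axis=0)
    if bs == 0:
        z = np.full(psth.counts.shape[1], np.nan)
    else:
        n = trials.size
        denom = bs if scale == "sd" else \
            bs * np.sqrt(1.0 / n + 1.0 / (n * base_bins.size))
        z = (mean_counts - bm) / denom
    return ZScoredPSTH(psth.unit_id, psth.bin_starts, z, bm, bs,
                       int(trials.size), scale)


def trial_zscores(psth: PSTHMatrix, trials=None) -> np.ndarray:
    """Single-trial counts standardized by the block's pooled baseline.

    Applies the z transform to the raw trial x bin counts (rather than
    the block mean): under a stationary unit the baseline-bin values are
    approximately standard normal, which makes this the natural
    null-calibration view of the transform.
    """
    trials = np.arange(psth.n_trials) if trials is None else np.asarray(trials)
    block = psth.counts[trials]
    baseline = block[:, psth.baseline_bins].ravel()
    bm = baseline.mean()
    bs = baseline.std(ddof=1) if baseline.size > 1 else 0.0
    if bs == 0:
        return np.full(block.shape, np.nan)
    return (block - bm) / bs


def population_psth(zpsths: list[ZScoredPSTH]) -> PopulationPSTH:
    """Average normalized PSTHs across units (mean and SEM per bin)."""
    if not zpsths:
        raise ValueError("need at least one unit")
    ref = zpsths[0].bin_starts
    for zp in zpsths[1:]:
        if zp.bin_starts.shape != ref.shape or not np.allclose(zp.bin_starts, ref):
            raise ValueError("units must share the bin structure")
    zmat = np.vstack([zp.z for zp in zpsths])
    n = zmat.shape[0]
    mean = zmat.mean(axis=0)
    sem = zmat.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
    return PopulationPSTH(ref, mean, sem, n)
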