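"""Core data containers shared across the analysis stages.

Spike times are seconds from session start; waveforms are fixed-length
sample vectors in arbitrary units; movement traces are binary per-sample
series from a beam-break-style activity detector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SpikeTrain",
    "WaveformSet",
    "MovementTrace",
    "read_spike_table",
    "write_spike_table",
]


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times of a single unit within one session."""

    unit_id: str
    session: str
    spike_times: np.ndarray  # strictly increasing, seconds

    def __post_init__(self) -> None:
        times = np.asarray(self.spike_times, dtype=float)
        object.__setattr__(self, "spike_times", times)
        if times.ndim != 1:
            raise ValueError("spike_times must be one-dimensional")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("spike_times must be strictly increasing")

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    def rate(self, duration: float) -> float:
        """Mean firing rate (Hz) over a known session duration."""
        if duration <= 0:
            raise ValueError("duration must be positive")
        return self.n_spikes / duration


@dataclass(frozen=True)
class WaveformSet:
    """Per-spike waveform snippets of one unit.

    ``spikes`` is an (n_spikes, n_samples) array; all snippets share the
    sampling rate and length, as produced by a fixed extraction window.
    """

    unit_id: str
    sample_rate: float
    spikes: np.ndarray

    def __post_init__(self) -> None:
        arr = np.atleast_2d(np.asarray(self.spikes, dtype=float))
        object.__setattr__(self, "spikes", arr)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError("need at least one spike with at least one sample")

    @property
    def n_spikes(self) -> int:
        return int(self.spikes.shape[0])

    @property
    def n_samples(self) -> int:
        return int(self.spikes.shape[1])

    def average(self) -> np.ndarray:
        return self.spikes.mean(axis=0)


@dataclass(frozen=True)
class MovementTrace:
    """Binary movement series: 1 where movement was detected, 0 where not."""

    sample_rate: float
    moving: np.ndarray = field(default_factory=lambda: np.ones(1, dtype=np.int8))

    def __post_init__(self) -> None:
        arr = np.asarray(self.moving).astype(np.int8)
        object.__setattr__(self, "moving", arr)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if arr.size == 0:
            raise ValueError("trace must contain at least one sample")
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("moving must be binary")

    @property
    def duration(self) -> float:
        return self.moving.size / self.sample_rate


def write_spike_table(trains: list[SpikeTrain], path) -> None:
    """Write spike trains as delimited text: unit_id, session, time_s."""
    rows = []
    for tr in trains:
        for t in tr.spike_times:
            rows.append((tr.unit_id, tr.session, repr(float(t))))
    df = pd.DataFrame(rows, columns=["unit_id", "session", "time_s"])
    df.to_csv(path, index=False)


def read_spike_table(path) -> list[SpikeTrain]:
    """Read a spike-time table back into per-unit, per-session trains."""
    df = pd.read_csv(path, float_precision="round_trip",
                     dtype={"unit_id": str, "session": str, "time_s": float})
    trains = []
    for (unit, session), grp in df.groupby(["unit_id", "session"], sort=True):
        trains.append(SpikeTrain(unit, session, np.sort(grp["time_s"].to_numpy())))
    return trains
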