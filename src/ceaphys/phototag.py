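"""Optogenetic identification of tagged units from light-pulse responses.

Arch-expressing units are identified by a significant change in firing
during 300-ms light pulses (120 pulses, 2-s inter-pulse gap by default):
per-pulse in-light spike counts are compared with duration-matched
immediately-pre-pulse baselines by a paired sign-flip permutation test.
The onset latency of the inhibition is then estimated by change-point
analysis of the pulse-averaged 1-ms rate series: the cumulative sum of
deviations from the series mean peaks at the last pre-change bin, and
the CUSUM range is referenced against permutations of the series for
significance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import SpikeTrain, WaveformSet
from .unit_qc import waveform_stability

__all__ = [
    "LightPulseTrain",
    "PhototagResult",
    "ChangePointResult",
    "light_response_test",
    "change_point_latency",
    "inhibition_magnitude",
    "evoked_waveform_similarity",
    "phototag_unit",
]


@dataclass(frozen=True)
class LightPulseTrain:
    """Onsets (s) of identical light pulses of one duration."""

    onsets: np.ndarray
    pulse_duration: float = 0.3

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets, dtype=float)
        object.__setattr__(self, "onsets", onsets)
        if onsets.size == 0:
            raise ValueError("need at least one pulse")
        if self.pulse_duration <= 0:
            raise ValueError("pulse_duration must be positive")
        gaps = np.diff(onsets)
        if np.any(gaps < self.pulse_duration):
            raise ValueError("pulses must not overlap")

    @classmethod
    def standard(cls, n_pulses: int = 120, inter_pulse_gap: float = 2.0,
                 pulse_duration: float = 0.3, start: float = 10.0,
                 ) -> "LightPulseTrain":
        """The tagging protocol: 300-ms pulses, 120 times, 2-s gaps."""
        period = pulse_duration + inter_pulse_gap
        return cls(start + period * np.arange(n_pulses), pulse_duration)

    @property
    def n_pulses(self) -> int:
        return int(self.onsets.size)


@dataclass(frozen=True)
class ChangePointResult:
    latency: float          # s from pulse onset; NaN when not significant
    p_value: float
    significant: bool
    cusum_range: float


@dataclass
class PhototagResult:
    unit_id: str
    responsive: bool
    sign: str               # excited | inhibited | none
    latency_s: float = math.nan
    magnitude_pct: float = math.nan
    p_value: float = math.nan
    waveform_r: float = math.nan


def _pulse_counts(spikes: SpikeTrain, starts: np.ndarray,
                  ends: np.ndarray) -> np.ndarray:
    t = spikes.spike_times
    return np.searchsorted(t, ends) - np.searchsorted(t, starts)


def light_response_test(spikes: SpikeTrain, pulses: LightPulseTrain,
                        n_perm: int = 1000, alpha: float = 0.01,
                        seed: int | None = None) -> PhototagResult:
    """Paired permutation test of in-light vs pre-pulse spike counts.

    Each pulse contributes the difference between its in-light count and
    the count in a duration-matched window immediately before the pulse;
    the null distribution is built by randomly flipping the signs of the
    paired differences.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    on = pulses.onsets
    d = pulses.pulse_duration
    diffs = (_pulse_counts(spikes, on, on + d)
             - _pulse_counts(spikes, on - d, on)).astype(float)
    obs = diffs.mean()
    rng = np.random.default_rng(seed)
    signs = rng.choice((-1.0, 1.0), size=(n_perm, diffs.size))
    null = (signs * diffs).mean(axis=1)
    p = (1.0 + np.sum(np.abs(null) >= abs(obs))) / (n_perm + 1.0)
    responsive = bool(p <= alpha and obs != 0)
    sign = "none" if not responsive else ("inhibited" if obs < 0 else "excited")
    return PhototagResult(spikes.unit_id, responsive, sign, p_value=float(p))


def pulse_aligned_counts(spikes: SpikeTrain, pulses: LightPulseTrain,
                         window=(-0.1, 0.3), bin_width: float = 0.001,
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Summed spike counts per peri-pulse bin; returns (edges, counts)."""
    n_bins = round((window[1] - window[0]) / bin_width)
    edges = window[0] + bin_width * np.arange(n_bins + 1)
    counts = np.zeros(n_bins, dtype=int)
    for on in pulses.onsets:
        counts += np.histogram(spikes.spike_times - on, bins=edges)[0]
    return edges, counts


def change_point_latency(spikes: SpikeTrain, pulses: LightPulseTrain,
                         bin_width: float = 0.001, window=(-0.1, 0.3),
                         n_boot: int = 1000, alpha: float = 0.05,
                         seed: int | None = None) -> ChangePointResult:
    """CUSUM change-point estimate of the light-response onset.

    The CUSUM of deviations from the series mean is extremal at the last
    bin before the (single) rate step, so the change time is the right
    edge of the argmax-|CUSUM| bin and the latency is that time minus
    the pulse onset.  Significance compares the observed CUSUM range
    with ranges from random permutations of the series.
    """
    edges, x = pulse_aligned_counts(spikes, pulses, window, bin_width)
    if x.size == 0:
        raise ValueError("empty pulse-aligned series")
    x = x.astype(float)
    s = np.cumsum(x - x.mean())
    obs_range = float(s.max() - s.min())
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_boot):
        xs = rng.permutation(x)
        ss = np.cumsum(xs - xs.mean())
        if ss.max() - ss.min() >= obs_range:
            exceed += 1
    p = (1.0 + exceed) / (n_boot + 1.0)
    significant = bool(p <= alpha)
    if not significant or obs_range == 0:
        return ChangePointResult(math.nan, float(p), False, obs_range)
    k = int(np.argmax(np.abs(s)))
    latency = float(edges[k + 1])
    return ChangePointResult(latency, float(p), True, obs_range)


def inhibition_magnitude(spikes: SpikeTrain, pulses: LightPulseTrain,
                         onset_latency: float = 0.0) -> float:
    """Percent rate change in light relative to the pre-pulse baseline.

    ``onset_latency`` (e.g. the change-point estimate) restricts the
    in-light window to ``[onset + latency, offset]`` so that a slow
    response onset does not dilute the measured modulation; the baseline
    is the duration-matched window immediately before each pulse.
    """
    on = pulses.onsets
    d = pulses.pulse_duration
    if not 0 <= onset_latency < d:
        raise ValueError("onset_latency must lie within the pulse")
    in_rate = _pulse_counts(spikes, on + onset_latency, on + d).sum() \
        / (pulses.n_pulses * (d - onset_latency))
    base_rate = _pulse_counts(spikes, on - d, on).sum() / (pulses.n_pulses * d)
    if base_rate == 0:
        raise ValueError("no baseline spikes: magnitude undefined")
    return 100.0 * (in_rate - base_rate) / base_rate


def evoked_waveform_similarity(spontaneous: WaveformSet,
                               in_light: WaveformSet) -> float:
    """Pearson r between the average spontaneous and light-period
    waveforms; near 1 when both spike sets come from the same neuron."""
    return waveform_stability(spontaneous.average(), in_light.average())


def phototag_unit(spikes: SpikeTrain, pulses: LightPulseTrain,
                  spontaneous_wf: WaveformSet | None = None,
                  light_wf: WaveformSet | None = None,
                  n_perm: int = 1000, alpha: float = 0.01,
                  n_boot: int = 1000, seed: int | None = None,
                  ) -> PhototagResult:
    """Full per-unit phototag summary: test, latency, magnitude, r."""
    res = light_response_test(spikes, pulses, n_perm, alpha, seed)
    if res.responsive:
        cp = change_point_latency(spikes, pulses, n_boot=n_boot, seed=seed)
        res.latency_s = cp.latency
        lat = cp.latency if cp.significant and 0 <= cp.latency \
            < pulses.pulse_duration else 0.0
        res.magnitude_pct = inhibition_magnitude(spikes, pulses,
                                                 onset_latency=lat)
    if spontaneous_wf is not None and light_wf is not None:
        res.waveform_r = evoked_waveform_similarity(spontaneous_wf, light_wf)
    return res
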