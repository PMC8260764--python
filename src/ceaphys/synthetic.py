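"""Synthetic recordings with the statistical structure the analyses assume.

The generator emulates the phenotypes recorded in central-amygdala
fear-extinction experiments: CElon units that acquire an excitatory
pip-locked response after conditioning, CEloff units that acquire an
inhibitory one, CEm output units that are excited, and non-responsive
units.  Spike trains are inhomogeneous Poisson processes whose rate is a
state- and class-dependent multiple of baseline inside a post-pip
response window; waveform clusters, Arch-style light inhibition, freezing
bout schedules and branching dendritic trees are generated alongside so
every downstream stage can be exercised end to end.

All draws are reproducible: identical seeds give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import MovementTrace, SpikeTrain, WaveformSet
from .morphology import SWC_DENDRITE, SWC_SOMA, NeuronMorphology
from .phototag import LightPulseTrain
from .protocol import ExperimentProtocol, pip_onsets

__all__ = [
    "PhenotypeSpec",
    "SimulationConfig",
    "DEFAULT_PHENOTYPES",
    "DEFAULT_STATE_SCHEDULE",
    "BEHAVIOURAL_STATES",
    "simulate_unit_spikes",
    "simulate_waveforms",
    "simulate_movement_trace",
    "simulate_phototag_unit",
    "simulate_morphology",
    "piecewise_constant_poisson",
    "straight_dendrite_plan",
    "y_tree_plan",
]

BEHAVIOURAL_STATES = ("habituation", "post_FC", "post_ext", "renewal",
                      "s1_persistent")
FEAR_STATES = ("post_FC", "renewal")

#: default refractory period enforced on simulated trains (s); violating
#: events are deleted so synthetic units pass the autocorrelogram check
DEFAULT_REFRACTORY_S = 0.002


@dataclass(frozen=True)
class PhenotypeSpec:
    """Rate model of one functional cell class.

    Inside ``[pip + latency + w0, pip + latency + w1]`` the rate is
    ``baseline_rate * state_gain[state]``; elsewhere it is the baseline.
    """

    cell_class: str                     # CElon | CEloff | CEm | nonresponsive
    region: str                         # CEl | CEm
    baseline_rate: float = 10.0         # Hz
    response_window: tuple[float, float] = (0.0, 0.25)  # s post-pip
    state_gain: dict = field(default_factory=dict)
    response_latency: float = 0.0       # s

    def __post_init__(self) -> None:
        if self.cell_class not in ("CElon", "CEloff", "CEm", "nonresponsive"):
            raise ValueError(f"unknown cell class {self.cell_class!r}")
        if self.region not in ("CEl", "CEm"):
            raise ValueError(f"unknown region {self.region!r}")
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be non-negative")
        if any(g < 0 for g in self.state_gain.values()):
            raise ValueError("state gains must be non-negative")
        for state in FEAR_STATES:
            g = self.state_gain.get(state)
            if g is None:
                continue
            if self.cell_class == "CEloff" and g > 1:
                raise ValueError("CEloff gain must be <= 1 in fear states")
            if self.cell_class in ("CElon", "CEm") and g < 1:
                raise ValueError(f"{self.cell_class} gain must be >= 1 "
                                 "in fear states")

    def gain(self, state: str) -> float:
        if state not in BEHAVIOURAL_STATES:
            raise ValueError(f"unknown behavioural state {state!r}")
        return float(self.state_gain.get(state, 1.0))


def _gains(hab, fc, ext, renewal=None, s1=None):
    renewal = fc if renewal is None else renewal
    s1 = fc if s1 is None else s1  # S1-like units keep their fear response
    return {"habituation": hab, "post_FC": fc, "post_ext": ext,
            "renewal": renewal, "s1_persistent": s1}


DEFAULT_PHENOTYPES = {
    "CElon": PhenotypeSpec("CElon", "CEl", state_gain=_gains(1.0, 3.0, 1.3)),
    "CEloff": PhenotypeSpec("CEloff", "CEl", state_gain=_gains(1.0, 0.2, 0.7)),
    "CEm": PhenotypeSpec("CEm", "CEm", state_gain=_gains(1.0, 3.0, 1.4)),
    "nonresponsive": PhenotypeSpec("nonresponsive", "CEl",
                                   state_gain=_gains(1.0, 1.0, 1.0)),
}

#: behavioural state of each session of the standard paradigm; early
#: extinction expresses the conditioned response, late extinction and
#: retrieval the extinguished one, renewal reinstates it
DEFAULT_STATE_SCHEDULE = {
    "habituation": "habituation",
    "fear_conditioning": "post_FC",
    "extinction1": "post_FC",
    "extinction2": "post_ext",
    "retrieval": "post_ext",
    "renewal": "renewal",
}


@dataclass(frozen=True)
class SimulationConfig:
    """Reproducible description of one synthetic dataset."""

    seed: int = 0
    units_per_class: dict = field(default_factory=lambda: {
        "CElon": 20, "CEloff": 10, "CEm": 10, "nonresponsive": 20})
    protocol_template: str = "standard"
    waveform_noise_sd: float = 0.05
    refractory_s: float = DEFAULT_REFRACTORY_S


def piecewise_constant_poisson(base_rate: float, window_starts, window_ends,
                               window_rate: float, duration: float,
                               rng: np.random.Generator,
                               refractory: float = 0.0) -> np.ndarray:
    """Poisson process at ``base_rate`` except inside the given windows.

    Implemented by thinning a homogeneous process at the maximum rate,
    which is exact for piecewise-constant intensities.  An optional
    absolute refractory period deletes violating events.
    """
    starts = np.asarray(window_starts, dtype=float)
    ends = np.asarray(window_ends, dtype=float)
    if starts.size and (np.any(np.diff(starts) <= 0)
                        or np.any(ends[:-1] > starts[1:])):
        raise ValueError("windows must be sorted and non-overlapping")
    if base_rate < 0 or window_rate < 0:
        raise ValueError("rates must be non-negative")
    max_rate = max(base_rate, window_rate)
    if max_rate == 0 or duration <= 0:
        return np.empty(0)
    n = rng.poisson(max_rate * duration)
    t = np.sort(rng.uniform(0.0, duration, size=n))
    if starts.size:
        idx = np.searchsorted(starts, t, side="right") - 1
        inside = (idx >= 0) & (t < ends[np.clip(idx, 0, len(ends) - 1)])
    else:
        inside = np.zeros(t.size, dtype=bool)
    p_accept = np.where(inside, window_rate / max_rate, base_rate / max_rate)
    t = t[rng.uniform(size=t.size) < p_accept]
    if refractory > 0 and t.size:
        keep = [0]
        last = t[0]
        for i in range(1, t.size):
            if t[i] - last >= refractory:
                keep.append(i)
                last = t[i]
        t = t[keep]
    return t


def simulate_unit_spikes(phenotype: PhenotypeSpec,
                         protocol: ExperimentProtocol,
                         state_schedule: dict[str, str],
                         seed: int,
                         unit_id: str = "unit0",
                         sessions: list[str] | None = None,
                         refractory: float = DEFAULT_REFRACTORY_S,
                         ) -> dict[str, SpikeTrain]:
    """Simulate one unit across sessions; returns a train per session.

    ``state_schedule`` maps every simulated session label to a
    behavioural state; the phenotype's gain for that state multiplies the
    baseline rate inside each pip's response window.
    """
    rng = np.random.default_rng(seed)
    labels = [s.label for s in protocol.sessions] if sessions is None else sessions
    out: dict[str, SpikeTrain] = {}
    for label in labels:
        if label not in state_schedule:
            raise ValueError(f"no behavioural state assigned to session "
                             f"{label!r}")
        sess = protocol.session(label)
        g = phenotype.gain(state_schedule[label])
        w0, w1 = phenotype.response_window
        lat = phenotype.response_latency
        pips = pip_onsets(protocol, label)
        starts = pips + lat + w0
        ends = pips + lat + w1
        t = piecewise_constant_poisson(
            phenotype.baseline_rate, starts, ends,
            phenotype.baseline_rate * g, sess.duration, rng,
            refractory=refractory)
        out[label] = SpikeTrain(unit_id, label, t)
    return out


def simulate_waveforms(templates, n_per_template: int, noise_sd: float,
                       seed: int, sample_rate: float = 40_000.0,
                       ) -> list[WaveformSet]:
    """Each spike is its template plus i.i.d. Gaussian noise per sample."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    templates = [np.asarray(t, dtype=float) for t in templates]
    if any(t.size == 0 for t in templates):
        raise ValueError("templates must be non-empty")
    if len({t.size for t in templates}) > 1:
        raise ValueError("templates must share a length")
    rng = np.random.default_rng(seed)
    out = []
    for i, tpl in enumerate(templates):
        spikes = tpl[None, :] + rng.normal(0.0, noise_sd,
                                           size=(n_per_template, tpl.size))
        out.append(WaveformSet(f"wf{i}", sample_rate, spikes))
    return out


def simulate_movement_trace(immobility_intervals, duration: float,
                            sample_rate: float = 10.0,
                            seed: int | None = None,
                            flip_prob: float = 0.0) -> MovementTrace:
    """Binary trace: movement everywhere except the scheduled intervals.

    ``flip_prob`` optionally flips samples at random (detector noise);
    it is off by default so schedules round-trip exactly through the
    freezing scorer.
    """
    iv = sorted((float(a), float(b)) for a, b in immobility_intervals)
    for (a0, b0), (a1, _) in zip(iv, iv[1:]):
        if a1 < b0:
            raise ValueError("immobility intervals must not overlap")
    for a, b in iv:
        if a < 0 or b > duration or b < a:
            raise ValueError("intervals must lie within the epoch")
    n = int(round(duration * sample_rate))
    moving = np.ones(n, dtype=np.int8)
    times = np.arange(n) / sample_rate
    for a, b in iv:
        moving[(times >= a) & (times < b)] = 0
    if flip_prob > 0:
        rng = np.random.default_rng(seed)
        flip = rng.uniform(size=n) < flip_prob
        moving[flip] = 1 - moving[flip]
    return MovementTrace(sample_rate, moving)


def simulate_phototag_unit(baseline_hz: float, inhibited_hz: float,
                           latency_s: float, pulses: LightPulseTrain,
                           seed: int, duration: float | None = None,
                           unit_id: str = "tagged0",
                           refractory: float = 0.0) -> SpikeTrain:
    """Arch-style unit: baseline Poisson, suppressed from pulse onset +
    latency to pulse offset."""
    if baseline_hz < 0 or inhibited_hz < 0:
        raise ValueError("rates must be non-negative")
    if latency_s < 0:
        raise ValueError("latency must be non-negative")
    if latency_s > pulses.pulse_duration:
        raise ValueError("latency exceeds the pulse duration")
    if duration is None:
        duration = float(pulses.onsets[-1] + pulses.pulse_duration + 2.0)
    rng = np.random.default_rng(seed)
    starts = pulses.onsets + latency_s
    ends = pulses.onsets + pulses.pulse_duration
    t = piecewise_constant_poisson(baseline_hz, starts, ends, inhibited_hz,
                                   duration, rng, refractory=refractory)
    return SpikeTrain(unit_id, "phototag", t)


# -- morphologies -----------------------------------------------------------

def simulate_morphology(branch_plan, jitter_sd: float = 0.0,
                        seed: int | None = None) -> NeuronMorphology:
    """Build an SWC-serializable tree from a branch plan.

    ``branch_plan`` is a list of ``(parent_index, x, y, z)`` rows, the
    first of which must be the soma with parent -1.  Optional Gaussian
    jitter perturbs non-soma positions; with jitter disabled the output
    is deterministic.
    """
    plan = list(branch_plan)
    if not plan or plan[0][0] != -1:
        raise ValueError("first plan row must be the soma with parent -1")
    n = len(plan)
    parent = np.array([row[0] for row in plan], dtype=int)
    if np.any(parent[1:] < 0) or np.any(parent[1:] >= np.arange(1, n)):
        raise ValueError("parents must precede children and form a tree")
    xyz = np.array([[row[1], row[2], row[3]] for row in plan], dtype=float)
    if jitter_sd > 0:
        rng = np.random.default_rng(seed)
        xyz[1:] += rng.normal(0.0, jitter_sd, size=(n - 1, 3))
    types = np.full(n, SWC_DENDRITE)
    types[0] = SWC_SOMA
    return NeuronMorphology(ids=np.arange(1, n + 1), types=types, xyz=xyz,
                            radius=np.full(n, 0.5), parent=parent)


def straight_dendrite_plan(length: float = 95.0):
    """Soma plus a single radial dendrite of the given length."""
    return [(-1, 0.0, 0.0, 0.0), (0, length, 0.0, 0.0)]


def y_tree_plan(trunk: float = 25.0, branch: float = 20.0,
                half_angle_deg: float = 20.0):
    """Soma, a radial trunk, and two symmetric daughter branches."""
    th = np.deg2rad(half_angle_deg)
    dx, dy = branch * np.cos(th), branch * np.sin(th)
    return [
        (-1, 0.0, 0.0, 0.0),
        (0, trunk, 0.0, 0.0),
        (1, trunk + dx, dy, 0.0),
        (1, trunk + dx, -dy, 0.0),
    ]
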