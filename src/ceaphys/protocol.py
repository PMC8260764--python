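"""Behavioural experiment timelines as typed event sequences.

A protocol is an ordered list of sessions (habituation, fear conditioning,
extinction, retrieval, renewal, ...), each an ordered list of stimulus
events.  The conditioned stimulus (CS) is a 30-s train of 50-ms sound pips
repeated at 0.9 Hz; during conditioning a foot-shock US starts at CS
offset; in optogenetic extinction sessions each pip of the stimulated CSs
carries a light pulse opening 50 ms before pip onset and lasting 350 ms.

Conventions (recorded here because the timeline maths depends on them):

* the first pip coincides with CS onset and pip *k* starts at ``k / rate``;
* a pip is included iff it ends on or before CS offset, which yields 27
  pips per standard 30-s CS and 108 pips per 4-CS block;
* times are seconds, intervals half-open ``[onset, onset + duration)``;
* inter-trial intervals are drawn uniformly from 20-180 s with a
  caller-supplied seed and never affect pip counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "StimulusEvent",
    "Session",
    "ExperimentProtocol",
    "BlockSpec",
    "BlockEpoch",
    "build_protocol",
    "pip_onsets",
    "block_epochs",
    "write_event_table",
    "read_event_table",
    "TEMPLATES",
]

EVENT_KINDS = ("cs", "pip", "us", "light")
SESSION_LABELS = (
    "habituation",
    "fear_conditioning",
    "extinction1",
    "extinction2",
    "retrieval",
    "renewal",
    "opto_extinction",
    "custom",
)

ITI_RANGE_S = (20.0, 180.0)
US_DURATION_S = 1.0
LIGHT_LEAD_S = 0.05     # light opens 50 ms before pip onset
LIGHT_DURATION_S = 0.35  # -50 ms .. +300 ms around the pip


@dataclass(frozen=True)
class StimulusEvent:
    kind: str
    onset: float
    duration: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.onset < 0 or self.duration < 0:
            raise ValueError("onset and duration must be non-negative")

    @property
    def offset(self) -> float:
        return self.onset + self.duration


@dataclass(frozen=True)
class Session:
    label: str
    context: str
    events: tuple[StimulusEvent, ...] = ()

    def __post_init__(self) -> None:
        if self.label not in SESSION_LABELS:
            raise ValueError(f"unknown session label {self.label!r}")
        if self.context not in ("A", "B"):
            raise ValueError("context must be 'A' or 'B'")
        ev = tuple(self.events)
        object.__setattr__(self, "events", ev)
        onsets = [e.onset for e in ev]
        if onsets != sorted(onsets):
            raise ValueError("events must be sorted by onset")
        # every pip must lie within some cs event
        cs = [e for e in ev if e.kind == "cs"]
        for p in (e for e in ev if e.kind == "pip"):
            if not any(c.onset <= p.onset and p.offset <= c.offset for c in cs):
                raise ValueError("pip event outside any cs event")

    def events_of(self, kind: str, label: str | None = None):
        return [
            e
            for e in self.events
            if e.kind == kind and (label is None or e.label == label)
        ]

    @property
    def duration(self) -> float:
        return max((e.offset for e in self.events), default=0.0) + 60.0


@dataclass(frozen=True)
class ExperimentProtocol:
    sessions: tuple[Session, ...]
    cs_frequency_hz: float = 0.9
    cs_duration_s: float = 30.0
    pip_duration_s: float = 0.05

    def __post_init__(self) -> None:
        object.__setattr__(self, "sessions", tuple(self.sessions))
        labels = [s.label for s in self.sessions]
        if len(labels) != len(set(labels)):
            raise ValueError("session labels must be unique")
        for name in ("cs_frequency_hz", "cs_duration_s", "pip_duration_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    def session(self, label: str) -> Session:
        for s in self.sessions:
            if s.label == label:
                return s
        raise KeyError(f"no session labelled {label!r}")


@dataclass(frozen=True)
class BlockSpec:
    """Number of consecutive CS presentations averaged together."""

    block_size: int = 4

    def __post_init__(self) -> None:
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")


@dataclass(frozen=True)
class BlockEpoch:
    cs_indices: tuple[int, ...]
    partial: bool = False


def _pip_times(cs_onset: float, cs_duration: float, rate: float,
               pip_duration: float) -> list[float]:
    """Pip onsets for one CS: first at CS onset, then every 1/rate, while
    the whole pip fits inside the CS."""
    if cs_duration < pip_duration:
        return []
    n = int(math.floor((cs_duration - pip_duration) * rate)) + 1
    return [cs_onset + k / rate for k in range(n)]


def _cs_with_pips(onset: float, label: str, proto_params: dict,
                  light: bool = False) -> list[StimulusEvent]:
    ev = [StimulusEvent("cs", onset, proto_params["cs_duration_s"], label)]
    for p in _pip_times(onset, proto_params["cs_duration_s"],
                        proto_params["cs_frequency_hz"],
                        proto_params["pip_duration_s"]):
        if light:
            ev.append(StimulusEvent("light", p - LIGHT_LEAD_S,
                                    LIGHT_DURATION_S, label))
        ev.append(StimulusEvent("pip", p, proto_params["pip_duration_s"], label))
    return ev


def _session(label: str, context: str, cs_plan: list[tuple[str, bool, bool]],
             params: dict, rng: np.random.Generator) -> Session:
    """Build one session.  ``cs_plan`` is a list of (cs_label, with_us,
    with_light) tuples; ITIs (CS offset to next CS onset) drawn 20-180 s."""
    events: list[StimulusEvent] = []
    t = float(rng.uniform(*ITI_RANGE_S))
    for cs_label, with_us, with_light in cs_plan:
        events.extend(_cs_with_pips(t, cs_label, params, light=with_light))
        cs_off = t + params["cs_duration_s"]
        if with_us:
            events.append(StimulusEvent("us", cs_off, US_DURATION_S, "shock"))
        t = cs_off + float(rng.uniform(*ITI_RANGE_S))
    events.sort(key=lambda e: (e.onset, EVENT_KINDS.index(e.kind)))
    return Session(label, context, tuple(events))


def _standard_template(params, rng, n_hab=4, n_fc=5, n_ext1=12, n_ext2=12,
                       n_ret=4, n_ren=4):
    plan = lambda n, us=False: [("CS", us, False)] * n  # noqa: E731
    return [
        _session("habituation", "B", plan(n_hab), params, rng),
        _session("fear_conditioning", "A", plan(n_fc, us=True), params, rng),
        _session("extinction1", "B", plan(n_ext1), params, rng),
        _session("extinction2", "B", plan(n_ext2), params, rng),
        _session("retrieval", "B", plan(n_ret), params, rng),
        _session("renewal", "A", plan(n_ren), params, rng),
    ]


def _discriminative_template(params, rng):
    hab = [("CS1", False, False), ("CS2", False, False)] * 4
    fc = [("CS1", True, False), ("CS2", True, False)] * 5
    ext1 = [("CS1", False, False)] * 16
    ext2 = [("CS1", False, False)] * 12 + [("CS2", False, False)] * 4
    return [
        _session("habituation", "B", hab, params, rng),
        _session("fear_conditioning", "A", fc, params, rng),
        _session("extinction1", "B", ext1, params, rng),
        _session("extinction2", "B", ext2, params, rng),
    ]


def _zif16_template(params, rng):
    fc = [("CS", True, False)] * 5
    ext = [("CS", False, False)] * 16
    return [
        _session("fear_conditioning", "A", fc, params, rng),
        _session("extinction1", "B", ext, params, rng),
    ]


def _opto_template(params, rng):
    fc = [("CS1", True, False)] * 5 + [("CS2", True, False)] * 5
    test = [("CS1", False, False)] * 4 + [("CS2", False, False)] * 4
    # light is coupled to every pip of the 5th..16th presentation of each CS
    ext = []
    for cs_label in ("CS1", "CS2"):
        for i in range(16):
            ext.append((cs_label, False, 5 <= i + 1 <= 16))
    return [
        _session("fear_conditioning", "A", fc, params, rng),
        _session("retrieval", "B", test, params, rng),
        _session("opto_extinction", "B", ext, params, rng),
    ]


TEMPLATES = {
    "standard": _standard_template,
    "discriminative": _discriminative_template,
    "zif16": _zif16_template,
    "opto_extinction": _opto_template,
}


def build_protocol(template: str = "standard", seed: int = 0,
                   cs_frequency_hz: float = 0.9, cs_duration_s: float = 30.0,
                   pip_duration_s: float = 0.05, **template_kwargs,
                   ) -> ExperimentProtocol:
    """Instantiate a named paradigm template.

    ``template_kwargs`` are forwarded to the template builder (e.g.
    ``n_ext1=0`` for an empty session in the standard paradigm).  ``seed``
    fixes the inter-trial-interval draws only.
    """
    if template not in TEMPLATES:
        raise ValueError(f"unknown template {template!r}; "
                         f"choose from {sorted(TEMPLATES)}")
    params = dict(cs_frequency_hz=cs_frequency_hz, cs_duration_s=cs_duration_s,
                  pip_duration_s=pip_duration_s)
    for k, v in params.items():
        if v <= 0:
            raise ValueError(f"{k} must be strictly positive")
    rng = np.random.default_rng(seed)
    sessions = TEMPLATES[template](params, rng, **template_kwargs)
    return ExperimentProtocol(tuple(sessions), **params)


def pip_onsets(protocol: ExperimentProtocol, session_label: str,
               cs_indices=None, cs_label: str | None = None) -> np.ndarray:
    """Sorted pip onset times for the selected CS presentations.

    ``cs_indices`` selects CS events by position (0-based, after the
    optional ``cs_label`` filter); ``None`` selects all.
    """
    sess = protocol.session(session_label)
    cs_events = sess.events_of("cs", cs_label)
    if cs_indices is not None:
        cs_events = [cs_events[i] for i in cs_indices]
    onsets: list[float] = []
    for cs in cs_events:
        onsets.extend(
            p.onset for p in sess.events_of("pip")
            if cs.onset <= p.onset and p.offset <= cs.offset
        )
    return np.sort(np.asarray(onsets, dtype=float))


def block_epochs(protocol: ExperimentProtocol, session_label: str,
                 block: BlockSpec = BlockSpec()) -> list[BlockEpoch]:
    """Partition a session's CS presentations into consecutive blocks.

    A trailing group smaller than ``block_size`` is retained and flagged
    ``partial``.
    """
    n_cs = len(protocol.session(session_label).events_of("cs"))
    if n_cs < 1:
        raise ValueError(f"session {session_label!r} has no CS presentations")
    out = []
    for start in range(0, n_cs, block.block_size):
        idx = tuple(range(start, min(start + block.block_size, n_cs)))
        out.append(BlockEpoch(idx, partial=len(idx) < block.block_size))
    return out


# -- event-table interchange ------------------------------------------------
# Delimited text, header `session,kind,onset_s,duration_s,label`.  One extra
# row per session (kind "session_meta" is not a stimulus kind; it is written
# first with the context in the label column) lets the reader restore the
# session context.  Floats are written with repr() so the round trip is
# bit-exact.

def write_event_table(protocol: ExperimentProtocol, path) -> None:
    rows = []
    for s in protocol.sessions:
        rows.append((s.label, "session_meta", repr(0.0), repr(0.0), s.context))
        for e in s.events:
            rows.append((s.label, e.kind, repr(e.onset), repr(e.duration), e.label))
    pd.DataFrame(
        rows, columns=["session", "kind", "onset_s", "duration_s", "label"]
    ).to_csv(path, index=False)


def read_event_table(path, cs_frequency_hz: float = 0.9,
                     cs_duration_s: float = 30.0,
                     pip_duration_s: float = 0.05) -> ExperimentProtocol:
    df = pd.read_csv(path, keep_default_na=False, float_precision="round_trip",
                     dtype={"session": str, "kind": str, "label": str,
                            "onset_s": float, "duration_s": float})
    sessions = []
    for label in df["session"].unique():
        grp = df[df["session"] == label]
        meta = grp[grp["kind"] == "session_meta"]
        context = meta["label"].iloc[0] if len(meta) else "B"
        events = tuple(
            StimulusEvent(r.kind, r.onset_s, r.duration_s, r.label)
            for r in grp.itertuples() if r.kind != "session_meta"
        )
        sessions.append(Session(label, context, events))
    return ExperimentProtocol(tuple(sessions), cs_frequency_hz,
                              cs_duration_s, pip_duration_s)
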