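"""3-D Sholl analysis and dendritic metrics on reconstructed neurons.

Morphologies are rooted trees in SWC convention: one node per sample
point, each with a 3-D position in micrometres, a radius and a parent
link; the root is the soma.  Sholl intersections are counted against
concentric spheres centred on the soma (Euclidean distance, 10-µm step by
default); a segment whose endpoints straddle a sphere counts one
intersection, and a tangential segment dipping inside a sphere with both
endpoints outside counts two.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "NeuronMorphology",
    "ShollProfile",
    "DendriteMetrics",
    "sholl_3d",
    "dendrite_metrics",
    "read_swc",
    "write_swc",
]

SWC_SOMA = 1
SWC_DENDRITE = 3


@dataclass(frozen=True)
class NeuronMorphology:
    """SWC-style tree: parallel arrays indexed by node.

    ``parent`` holds the index of each node's parent (-1 for the root);
    parents precede children, so a single forward pass visits the tree in
    topological order.
    """

    ids: np.ndarray        # SWC sample numbers
    types: np.ndarray      # SWC structure codes (1 soma, 3 dendrite)
    xyz: np.ndarray        # (n, 3) positions, µm
    radius: np.ndarray     # µm
    parent: np.ndarray     # index into the arrays, -1 for root

    def __post_init__(self) -> None:
        xyz = np.atleast_2d(np.asarray(self.xyz, dtype=float))
        object.__setattr__(self, "xyz", xyz)
        for name in ("ids", "types", "parent"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=int))
        object.__setattr__(self, "radius", np.asarray(self.radius, dtype=float))
        n = xyz.shape[0]
        if not (len(self.ids) == len(self.types) == len(self.radius)
                == len(self.parent) == n):
            raise ValueError("node arrays must have equal length")
        roots = np.flatnonzero(self.parent == -1)
        if len(roots) != 1 or roots[0] != 0:
            raise ValueError("tree must have exactly one root at index 0")
        if np.any(self.parent[1:] >= np.arange(1, n)):
            raise ValueError("each parent must precede its child (no cycles)")
        if np.any(self.parent[1:] < 0):
            raise ValueError("orphan node: only the root may lack a parent")
        if not np.isfinite(xyz).all():
            raise ValueError("positions must be finite")

    @property
    def n_nodes(self) -> int:
        return int(self.xyz.shape[0])

    @property
    def soma(self) -> np.ndarray:
        return self.xyz[0]

    def segments(self) -> np.ndarray:
        """Indices (child, parent) of every dendritic segment.

        Segments whose child node is soma-typed are skipped, so a
        multi-node soma contour does not contribute dendritic length.
        """
        child = np.arange(1, self.n_nodes)
        keep = self.types[child] != SWC_SOMA
        child = child[keep]
        return np.column_stack([child, self.parent[child]])


@dataclass(frozen=True)
class ShollProfile:
    radii: np.ndarray          # µm, strictly increasing
    intersections: np.ndarray  # counts per radius

    def __post_init__(self) -> None:
        object.__setattr__(self, "radii", np.asarray(self.radii, dtype=float))
        object.__setattr__(self, "intersections",
                           np.asarray(self.intersections, dtype=int))
        if np.any(np.diff(self.radii) <= 0):
            raise ValueError("radii must be strictly increasing")
        if np.any(self.intersections < 0):
            raise ValueError("intersection counts must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"radius_um": self.radii,
                             "intersections": self.intersections})


@dataclass(frozen=True)
class DendriteMetrics:
    total_length: float            # summed segment lengths, µm
    n_dendrites: int               # subtrees rooted at soma children
    n_terminal_branches: int       # branches ending at a tip
    terminal_branch_length: float  # summed tip-branch lengths, µm


def _segment_sphere_crossings(d0: float, d1: float, dmin: float,
                              r: float) -> int:
    """Crossings of one straight segment with the sphere of radius r.

    ``d0``/``d1`` are endpoint distances from the soma, ``dmin`` the
    minimum distance along the segment.
    """
    lo, hi = (d0, d1) if d0 <= d1 else (d1, d0)
    if lo < r <= hi:
        return 1
    if lo >= r and dmin < r:
        return 2  # dips inside and comes back out
    return 0


def sholl_3d(m: NeuronMorphology, step: float = 10.0,
             max_radius: float | None = None) -> ShollProfile:
    """Count dendritic intersections with concentric spheres round the soma."""
    if step <= 0:
        raise ValueError("step must be positive")
    segs = m.segments()
    soma = m.soma
    if len(segs) == 0:
        radii = np.array([step]) if max_radius is None else \
            np.arange(step, max_radius + 0.5 * step, step)
        return ShollProfile(radii, np.zeros(len(radii), dtype=int))

    a = m.xyz[segs[:, 1]] - soma   # parent end
    b = m.xyz[segs[:, 0]] - soma   # child end
    d0 = np.linalg.norm(a, axis=1)
    d1 = np.linalg.norm(b, axis=1)
    # closest point on each segment to the soma
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.clip(np.where(denom > 0, -np.einsum("ij,ij->i", a, ab) / denom, 0.0),
                    0.0, 1.0)
    dmin = np.linalg.norm(a + t[:, None] * ab, axis=1)

    reach = float(max(d0.max(), d1.max()))
    if max_radius is None:
        max_radius = reach
    radii = np.arange(step, max_radius + 0.5 * step, step)
    counts = np.zeros(len(radii), dtype=int)
    for i, r in enumerate(radii):
        counts[i] = sum(
            _segment_sphere_crossings(d0[k], d1[k], dmin[k], r)
            for k in range(len(segs))
        )
    return ShollProfile(radii, counts)


def dendrite_metrics(m: NeuronMorphology) -> DendriteMetrics:
    """Total dendritic length, dendrite count and terminal-branch stats.

    A *dendrite* is the subtree hanging off one soma child; a *branch* is
    the unbranched path between consecutive branch points (or soma/tip);
    terminal branches are those ending at a tip.
    """
    segs = m.segments()
    if len(segs) == 0:
        return DendriteMetrics(0.0, 0, 0, 0.0)
    lengths = np.linalg.norm(m.xyz[segs[:, 0]] - m.xyz[segs[:, 1]], axis=1)
    total = float(lengths.sum())
    seg_len = {int(c): float(l) for (c, p), l in zip(segs, lengths)}

    children: dict[int, list[int]] = {}
    for c, p in segs:
        children.setdefault(int(p), []).append(int(c))
    n_dendrites = len(children.get(0, []))

    tips = [int(c) for c, _ in segs if int(c) not in children]
    term_len = 0.0
    for tip in tips:
        # walk back until a branch point (>1 child) or the soma
        node = tip
        while True:
            term_len += seg_len[node]
            p = int(m.parent[node])
            if p == 0 or len(children.get(p, [])) > 1:
                break
            node = p
    return DendriteMetrics(total, n_dendrites, len(tips), term_len)


def read_swc(path) -> NeuronMorphology:
    """Read a standard SWC file (``id type x y z radius parent``)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            rows.append((int(parts[0]), int(parts[1]), float(parts[2]),
                         float(parts[3]), float(parts[4]), float(parts[5]),
                         int(parts[6])))
    if not rows:
        raise ValueError("empty SWC file")
    ids = np.array([r[0] for r in rows])
    index_of = {sid: i for i, sid in enumerate(ids)}
    parent = np.array([-1 if r[6] == -1 else index_of[r[6]] for r in rows])
    return NeuronMorphology(
        ids=ids,
        types=np.array([r[1] for r in rows]),
        xyz=np.array([[r[2], r[3], r[4]] for r in rows]),
        radius=np.array([r[5] for r in rows]),
        parent=parent,
    )


def write_swc(m: NeuronMorphology, path) -> None:
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for i in range(m.n_nodes):
            pid = -1 if m.parent[i] == -1 else m.ids[m.parent[i]]
            x, y, z = (repr(float(v)) for v in m.xyz[i])
            fh.write(f"{m.ids[i]} {m.types[i]} {x} {y} {z} "
                     f"{float(m.radius[i])!r} {pid}\n")
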