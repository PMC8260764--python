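"""Spike-sorting quality and unit-identity checks.

Cluster separation in waveform principal-component space is quantified
with the J3 statistic (between- over within-cluster scatter; higher is
better) and the Davies-Bouldin index (within-cluster scatter over
centroid separation; lower is better), referenced against an
artificial-cluster null built by randomly bisecting a centred
single-cloud of points.  Single-unit identity is checked with the
autocorrelogram refractory period, cross-day average-waveform
correlation, and cross-correlogram coincidence against other units to
reject duplicates picked up on multiple channels.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA

from .core import SpikeTrain, WaveformSet

__all__ = [
    "ClusterFeatures",
    "Correlogram",
    "QCReport",
    "NullDistributions",
    "waveform_features",
    "j3_statistic",
    "davies_bouldin",
    "artificial_cluster_null",
    "refractory_check",
    "waveform_stability",
    "duplicate_units",
    "correlogram",
]


@dataclass(frozen=True)
class ClusterFeatures:
    """Feature-space points with a cluster id per point."""

    points: np.ndarray   # (n, d)
    labels: np.ndarray   # (n,)

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "labels", np.asarray(self.labels))
        if len(self.labels) != pts.shape[0]:
            raise ValueError("one label per point required")

    @property
    def cluster_ids(self) -> np.ndarray:
        return np.unique(self.labels)


@dataclass(frozen=True)
class Correlogram:
    lag_edges: np.ndarray   # seconds, symmetric about 0
    counts: np.ndarray
    bin_width: float

    @property
    def lag_centers(self) -> np.ndarray:
        return 0.5 * (self.lag_edges[:-1] + self.lag_edges[1:])


@dataclass
class QCReport:
    unit_id: str
    j3: float | None = None
    db: float | None = None
    j3_null_quantile: float | None = None
    db_null_quantile: float | None = None
    refractory_violation_fraction: float | None = None
    stability_r: dict | None = None
    duplicate_of: str | None = None

    def to_json(self) -> str:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, float) and math.isinf(v):
                d[k] = "inf"
        return json.dumps(d)


def waveform_features(waveforms, n_components: int = 3) -> ClusterFeatures:
    """Project spikes onto the top principal components of the pooled
    spike-sample covariance (mean-centred).

    ``waveforms`` is a WaveformSet or a list of them; each set becomes
    one cluster label.
    """
    sets = [waveforms] if isinstance(waveforms, WaveformSet) else list(waveforms)
    spikes = np.vstack([w.spikes for w in sets])
    labels = np.concatenate([np.full(w.n_spikes, i) for i, w in enumerate(sets)])
    if spikes.shape[0] < 2:
        raise ValueError("need at least two spikes for feature projection")
    if n_components > spikes.shape[1]:
        raise ValueError("n_components exceeds samples per spike")
    scores = PCA(n_components=n_components).fit_transform(spikes)
    return ClusterFeatures(scores, labels)


def _scatter_terms(f: ClusterFeatures):
    mu = f.points.mean(axis=0)
    within = 0.0
    between = 0.0
    for cid in f.cluster_ids:
        pts = f.points[f.labels == cid]
        mu_c = pts.mean(axis=0)
        within += float(((pts - mu_c) ** 2).sum())
        between += len(pts) * float(((mu_c - mu) ** 2).sum())
    return within, between


def j3_statistic(f: ClusterFeatures) -> float:
    """Ratio of between-cluster to within-cluster scatter (squared
    Euclidean).  Point-mass clusters give +inf."""
    if len(f.cluster_ids) < 2:
        raise ValueError("J3 requires at least two clusters")
    j1, j2 = _scatter_terms(f)
    return math.inf if j1 == 0 else j2 / j1


def davies_bouldin(f: ClusterFeatures) -> float:
    """Davies-Bouldin index: mean over clusters of the worst-case
    (S_i + S_j) / ||mu_i - mu_j||, with S the mean distance to the
    centroid.  Coincident centroids give +inf."""
    ids = f.cluster_ids
    if len(ids) < 2:
        raise ValueError("DB requires at least two clusters")
    mus, spreads = [], []
    for cid in ids:
        pts = f.points[f.labels == cid]
        mu_c = pts.mean(axis=0)
        mus.append(mu_c)
        spreads.append(float(np.linalg.norm(pts - mu_c, axis=1).mean()))
    total = 0.0
    for i in range(len(ids)):
        worst = 0.0
        for j in range(len(ids)):
            if i == j:
                continue
            sep = float(np.linalg.norm(mus[i] - mus[j]))
            if sep == 0:
                return math.inf
            worst = max(worst, (spreads[i] + spreads[j]) / sep)
        total += worst
    return total / len(ids)


@dataclass(frozen=True)
class NullDistributions:
    j3: np.ndarray
    db: np.ndarray

    def quantile_of(self, which: str, value: float) -> float:
        """Fraction of null draws at or below the observed value."""
        draws = getattr(self, which)
        return float(np.mean(draws <= value))


def artificial_cluster_null(cloud, n_splits: int = 1000,
                            seed: int | None = None) -> NullDistributions:
    """Null J3/DB from random bisections of one centred cloud.

    Mirrors the control of defining two artificial clusters on a channel
    with no isolatable unit: the cloud is centred, then split by a
    hyperplane through the centroid with orientation uniform on the
    sphere; degenerate one-sided splits are redrawn.
    """
    pts = np.atleast_2d(np.asarray(cloud, dtype=float))
    if pts.shape[0] < 4:
        raise ValueError("null cloud needs at least 4 points")
    if n_splits < 1:
        raise ValueError("n_splits must be >= 1")
    pts = pts - pts.mean(axis=0)
    rng = np.random.default_rng(seed)
    j3s = np.empty(n_splits)
    dbs = np.empty(n_splits)
    for i in range(n_splits):
        while True:
            w = rng.normal(size=pts.shape[1])
            w /= np.linalg.norm(w)
            labels = (pts @ w > 0).astype(int)
            if 0 < labels.sum() < len(labels):
                break
        f = ClusterFeatures(pts, labels)
        j3s[i] = j3_statistic(f)
        dbs[i] = davies_bouldin(f)
    return NullDistributions(j3s, dbs)


def correlogram(ref: SpikeTrain, target: SpikeTrain, max_lag: float = 0.05,
                bin_width: float = 0.001,
                remove_self_pairs: bool = False) -> Correlogram:
    """Histogram of target minus reference spike-time lags in
    [-max_lag, +max_lag).  ``remove_self_pairs`` drops the per-spike
    zero-lag pair of a train against itself (autocorrelogram use)."""
    edges = np.arange(-max_lag, max_lag + 0.5 * bin_width, bin_width)
    a, b = ref.spike_times, target.spike_times
    lo = np.searchsorted(b, a - max_lag, side="left")
    hi = np.searchsorted(b, a + max_lag, side="left")
    n_pairs = hi - lo
    # flat index into b of every (ref, target) pair within max_lag
    starts = np.concatenate([[0], np.cumsum(n_pairs)[:-1]])
    flat = np.arange(int(n_pairs.sum())) + np.repeat(lo - starts, n_pairs)
    lags = b[flat] - np.repeat(a, n_pairs)
    counts = np.histogram(lags, bins=edges)[0]
    if remove_self_pairs:
        zero_bin = np.searchsorted(edges, 0.0, side="right") - 1
        counts[zero_bin] -= a.size
    return Correlogram(edges, counts, bin_width)


def refractory_check(spikes: SpikeTrain, refractory: float = 0.001,
                     ) -> tuple[float | None, Correlogram]:
    """Fraction of inter-spike intervals below the refractory period,
    plus the +/-50-ms autocorrelogram at 1-ms bins.

    With fewer than two spikes the fraction is undefined (None).
    """
    acg = correlogram(spikes, spikes, remove_self_pairs=True)
    if spikes.n_spikes < 2:
        return None, acg
    isi = np.diff(spikes.spike_times)
    return float(np.mean(isi < refractory)), acg


def waveform_stability(avg_a, avg_b) -> float:
    """Pearson correlation between two average waveforms (e.g. across
    training days, or spontaneous vs light-evoked spikes)."""
    a = np.asarray(avg_a, dtype=float)
    b = np.asarray(avg_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("waveforms must have equal length")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant waveform has no defined correlation")
    return float(stats.pearsonr(a, b).statistic)


def duplicate_units(train_a: SpikeTrain, train_b: SpikeTrain,
                    coincidence_window: float = 0.001,
                    min_spikes: int = 50,
                    flank_range: tuple[float, float] = (0.010, 0.050),
                    n_sd: float = 5.0,
                    ) -> tuple[bool | None, Correlogram]:
    """Flag two trains as the same neuron seen on two channels.

    The cross-correlogram (+/-50 ms, 1-ms bins) is compared against its
    10-50 ms flanks: a zero-lag bin exceeding flank mean + ``n_sd``
    flank standard deviations marks a coincidence excess.  Returns
    (flag, correlogram); the flag is None (indeterminate) when either
    train has fewer than ``min_spikes`` spikes.
    """
    ccg = correlogram(train_a, train_b)
    if train_a.n_spikes < min_spikes or train_b.n_spikes < min_spikes:
        return None, ccg
    centers = ccg.lag_centers
    central = np.abs(centers) < coincidence_window
    flank = (np.abs(centers) >= flank_range[0]) \
        & (np.abs(centers) <= flank_range[1])
    fm = ccg.counts[flank].mean()
    fs = ccg.counts[flank].std(ddof=1)
    flag = bool(np.any(ccg.counts[central] > fm + n_sd * fs))
    return flag, ccg
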