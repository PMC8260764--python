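"""Freezing quantification and the repeated-measures statistics.

Freezing is scored from binary movement traces with the beam-break
rule: an animal is freezing when no movement is detected for at least
2 s, and every qualifying immobility bout contributes its entire
duration.  Per-CS and no-CS epoch percentages feed block averages, a
50% cut-off splits subjects by spontaneous recovery at retrieval, and
group comparisons use one- or two-way repeated-measures ANOVA with
Bonferroni-adjusted paired post-hoc t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

from .core import MovementTrace
from .protocol import BlockSpec, ExperimentProtocol

__all__ = [
    "FreezingScore",
    "AnovaResult",
    "score_freezing",
    "freezing_cutoff_filter",
    "rm_anova",
    "bonferroni_posthoc",
    "paired_t",
    "cs_epochs",
    "block_average",
]

MIN_BOUT_S = 2.0


@dataclass(frozen=True)
class FreezingScore:
    """Percent freezing per labelled epoch, in epoch order."""

    labels: tuple[str, ...]
    percent: np.ndarray

    def __post_init__(self) -> None:
        pct = np.asarray(self.percent, dtype=float)
        object.__setattr__(self, "percent", pct)
        object.__setattr__(self, "labels", tuple(self.labels))
        if np.any((pct < 0) | (pct > 100)):
            raise ValueError("percentages must lie in [0, 100]")

    def __getitem__(self, label: str) -> float:
        return float(self.percent[self.labels.index(label)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"label": self.labels,
                             "percent_freezing": self.percent})


@dataclass(frozen=True)
class AnovaResult:
    """Within-subject ANOVA effects plus an optional post-hoc table."""

    effects: pd.DataFrame           # factor, F, df1, df2, p
    posthoc: pd.DataFrame | None = None

    def effect(self, factor: str) -> pd.Series:
        hit = self.effects[self.effects["factor"] == factor]
        if hit.empty:
            raise KeyError(f"no effect named {factor!r}")
        return hit.iloc[0]


def _freezing_intervals(trace: MovementTrace, min_bout: float):
    """Maximal immobility runs of duration >= min_bout, as (start, end)."""
    m = trace.moving
    padded = np.concatenate([[1], m, [1]])
    starts = np.flatnonzero(np.diff(padded) == -1)
    ends = np.flatnonzero(np.diff(padded) == 1)
    fs = trace.sample_rate
    out = []
    for s, e in zip(starts, ends):
        if (e - s) / fs >= min_bout - 1e-9:
            out.append((s / fs, e / fs))
    return out


def score_freezing(trace: MovementTrace, epochs,
                   min_bout: float = MIN_BOUT_S) -> FreezingScore:
    """Percent freezing per epoch.

    ``epochs`` is a list of ``(start_s, end_s, label)``.  A qualifying
    immobility bout contributes its full duration; bouts spanning an
    epoch boundary contribute the overlapping part to each side.
    """
    if min_bout <= 0:
        raise ValueError("min_bout must be positive")
    bouts = _freezing_intervals(trace, min_bout)
    labels, pcts = [], []
    for start, end, label in epochs:
        if end <= start:
            raise ValueError(f"zero-length epoch {label!r}")
        if start < 0 or end > trace.duration + 1e-9:
            raise ValueError(f"epoch {label!r} outside the trace")
        frozen = sum(max(0.0, min(end, b1) - max(start, b0))
                     for b0, b1 in bouts)
        labels.append(label)
        pcts.append(min(100.0, 100.0 * frozen / (end - start)))
    return FreezingScore(tuple(labels), np.asarray(pcts))


def freezing_cutoff_filter(retrieval_scores: dict, cutoff: float = 50.0,
                           ) -> list:
    """Subjects below the spontaneous-recovery cut-off (strict ``<``),
    i.e. the extinction-memory subset retained for renewal analyses."""
    if not retrieval_scores:
        raise ValueError("no subjects given")
    return [s for s, pct in retrieval_scores.items() if pct < cutoff]


def cs_epochs(protocol: ExperimentProtocol, session_label: str,
              include_baseline: bool = True):
    """Epoch list for one session: optional pre-first-CS ``no_CS``
    baseline, then one epoch per CS presentation."""
    sess = protocol.session(session_label)
    cs = sess.events_of("cs")
    epochs = []
    if include_baseline and cs and cs[0].onset > 0:
        epochs.append((0.0, cs[0].onset, "no_CS"))
    for i, c in enumerate(cs):
        epochs.append((c.onset, c.offset, f"CS{i + 1}"))
    return epochs


def block_average(score: FreezingScore, block: BlockSpec = BlockSpec(),
                  prefix: str = "CS") -> FreezingScore:
    """Average consecutive per-CS percentages in blocks (of 4 CSs by
    default); non-CS epochs pass through unchanged."""
    cs_labels = [l for l in score.labels if l.startswith(prefix)]
    other = [(l, score[l]) for l in score.labels if not l.startswith(prefix)]
    labels, pcts = [l for l, _ in other], [p for _, p in other]
    for start in range(0, len(cs_labels), block.block_size):
        chunk = cs_labels[start:start + block.block_size]
        labels.append(f"{prefix}_block{start // block.block_size + 1}")
        pcts.append(float(np.mean([score[l] for l in chunk])))
    return FreezingScore(tuple(labels), np.asarray(pcts))


def rm_anova(data: pd.DataFrame, dv: str, within, subject: str,
             correction: bool = False) -> AnovaResult:
    """One- or two-way repeated-measures ANOVA on a long-format table.

    ``within`` is one factor name or a list of two.  The design must be
    complete and balanced.  Sphericity (Greenhouse-Geisser) correction
    is off by default and available behind ``correction``.
    """
    within_list = [within] if isinstance(within, str) else list(within)
    if not 1 <= len(within_list) <= 2:
        raise ValueError("one or two within factors supported")
    if data[subject].nunique() < 2:
        raise ValueError("need at least two subjects")
    counts = data.groupby([subject] + within_list, observed=True)[dv].count()
    n_cells = data[subject].nunique() * int(np.prod(
        [data[f].nunique() for f in within_list]))
    if len(counts) != n_cells or counts.nunique() > 1:
        raise ValueError("design must be complete and balanced")
    table = pg.rm_anova(data=data, dv=dv, within=within_list, subject=subject,
                        correction=correction, detailed=True)
    pcol = "p_GG_corr" if correction and "p_GG_corr" in table else "p_unc"
    if "ddof1" in table:        # two-way layout
        effects_src = table
        df1 = effects_src["ddof1"].to_numpy(dtype=int)
        df2 = effects_src["ddof2"].to_numpy(dtype=int)
    else:                       # one-way layout: error row carries df2
        err_df = int(table.loc[table["Source"] == "Error", "DF"].iloc[0])
        effects_src = table[table["Source"] != "Error"]
        df1 = effects_src["DF"].to_numpy(dtype=int)
        df2 = np.full(len(effects_src), err_df)
    effects = pd.DataFrame({
        "factor": effects_src["Source"].to_numpy(),
        "F": effects_src["F"].to_numpy(dtype=float),
        "df1": df1,
        "df2": df2,
        "p": effects_src[pcol].to_numpy(dtype=float),
    }).dropna(subset=["F"]).reset_index(drop=True)
    return AnovaResult(effects)


def paired_t(a, b) -> tuple[float, int, float]:
    """Two-sided paired Student t-test; returns (t, df, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length samples of size >= 2")
    d = a - b
    if d.std(ddof=1) == 0:
        if d.mean() == 0:
            return 0.0, a.size - 1, 1.0
        raise ValueError("zero variance of non-zero differences")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), a.size - 1, float(res.pvalue)


def bonferroni_posthoc(data: pd.DataFrame, dv: str, within: str,
                       subject: str, reference: str) -> pd.DataFrame:
    """Paired t of every condition against the reference, Bonferroni
    adjusted: p_adj = min(1, k * p_raw) over the k comparisons."""
    levels = [l for l in data[within].unique() if l != reference]
    if not levels:
        raise ValueError("reference condition missing or alone")
    wide = data.pivot_table(index=subject, columns=within, values=dv)
    if reference not in wide:
        raise ValueError(f"reference level {reference!r} not found")
    k = len(levels)
    rows = []
    for lv in levels:
        t, df, p = paired_t(wide[lv].to_numpy(), wide[reference].to_numpy())
        rows.append({"comparison": f"{lv} vs {reference}", "t": t, "df": df,
                     "p_raw": p, "p_adj": min(1.0, k * p)})
    return pd.DataFrame(rows)
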