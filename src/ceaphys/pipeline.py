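"""End-to-end orchestration: simulate -> QC -> PSTH -> classify ->
phototag -> behaviour -> report.

The default run emulates the standard fear-extinction study on synthetic
data: a population of CElon / CEloff / CEm / non-responsive units
recorded over habituation and two extinction sessions, classified from
the first 4-CS block of extinction day 1, with spike-sorting QC and
duplicate rejection applied first, plus phototagged Arch units and
per-subject freezing behaviour.  Every unit appears in the report
exactly once, either classified or excluded with a reason; identical
configurations reproduce every table bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from . import behavior as beh
from . import classify as cls
from . import phototag as pt
from . import psth as ps
from . import synthetic as syn
from . import unit_qc as qc
from .protocol import ExperimentProtocol, block_epochs, build_protocol, \
    pip_onsets

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "ConfigError"]


class ConfigError(ValueError):
    """Raised when a run configuration fails validation."""


#: mean percent freezing during CS at the start/end of each scored
#: session, used to build subjects' immobility-bout schedules; values
#: follow the group means of the emulated paradigm
FREEZING_LEVELS = {
    "habituation": (26.0, 26.0),
    "extinction1": (62.0, 45.0),
    "extinction2": (45.0, 34.0),
}
NO_CS_FREEZING = 20.0
FREEZING_SUBJECT_SD = 8.0
FREEZING_EPOCH_SD = 6.0


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    units_per_class: dict = field(default_factory=lambda: {
        "CElon": 20, "CEloff": 10, "CEm": 10, "nonresponsive": 20})
    template: str = "standard"
    sessions: tuple = ("habituation", "extinction1", "extinction2")
    state_schedule: dict = field(
        default_factory=lambda: dict(syn.DEFAULT_STATE_SCHEDULE))
    baseline_rate: float = 10.0
    waveform_noise_sd: float = 0.05
    n_subjects: int = 8
    n_tagged: int = 3
    classification: cls.ClassificationParams = cls.ClassificationParams()
    refractory_max_fraction: float = 0.01

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.units_per_class.values()):
            raise ConfigError("unit counts must be non-negative")
        unknown = set(self.units_per_class) - set(syn.DEFAULT_PHENOTYPES)
        if unknown:
            raise ConfigError(f"unknown cell classes {sorted(unknown)}")
        for s in self.sessions:
            if s not in self.state_schedule:
                raise ConfigError(f"session {s!r} has no behavioural state")

    @classmethod
    def from_dict(cls_, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "classification" in d and isinstance(d["classification"], dict):
            d["classification"] = cls.ClassificationParams(**d["classification"])
        if "sessions" in d:
            d["sessions"] = tuple(d["sessions"])
        try:
            return cls_(**d)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc


@dataclass
class RunReport:
    config: dict
    seed: int
    version: str
    units: pd.DataFrame             # unit_id, true_class, region, disposition
    classification: pd.DataFrame
    confusion: pd.DataFrame         # true class x assigned class
    qc_channels: pd.DataFrame
    phototag: pd.DataFrame
    freezing: pd.DataFrame
    freezing_anova: pd.DataFrame
    freezing_posthoc: pd.DataFrame
    population_psth: pd.DataFrame

    def per_class_recovery(self) -> dict[str, float]:
        """Confusion-matrix diagonal as a fraction of each true class."""
        out = {}
        for true_class, row in self.confusion.iterrows():
            total = row.sum()
            out[true_class] = float(row.get(true_class, 0) / total) if total else np.nan
        return out

    def write(self, out_dir) -> None:
        from pathlib import Path
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "run.json").write_text(json.dumps(
            {"config": self.config, "seed": self.seed,
             "version": self.version}, indent=2, default=str))
        for name in ("units", "classification", "confusion", "qc_channels",
                     "phototag", "freezing", "freezing_anova",
                     "freezing_posthoc", "population_psth"):
            df = getattr(self, name)
            df.to_csv(out / f"{name}.csv",
                      index=(name == "confusion"))


def _make_units(config: PipelineConfig):
    units = []
    region_cycle = {"nonresponsive": ["CEl", "CEm"]}
    i = 0
    for cell_class in ("CElon", "CEloff", "CEm", "nonresponsive"):
        for k in range(config.units_per_class.get(cell_class, 0)):
            spec = syn.DEFAULT_PHENOTYPES[cell_class]
            region = spec.region
            if cell_class in region_cycle:
                region = region_cycle[cell_class][k % 2]
            spec = replace(spec, region=region,
                           baseline_rate=config.baseline_rate)
            units.append({"unit_id": f"u{i:03d}", "true_class": cell_class,
                          "region": region, "phenotype": spec})
            i += 1
    return units


_WAVEFORM_TEMPLATES = (
    np.sin(np.linspace(0, 2 * np.pi, 32)) * np.hanning(32),
    -np.sin(np.linspace(0, 3 * np.pi, 32)) * np.hanning(32),
)


def _simulate_freezing(protocol: ExperimentProtocol, config: PipelineConfig,
                       rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for subj in range(config.n_subjects):
        offset = rng.normal(0.0, FREEZING_SUBJECT_SD)
        for session, (lvl0, lvl1) in FREEZING_LEVELS.items():
            if session not in config.sessions:
                continue
            sess = protocol.session(session)
            epochs = beh.cs_epochs(protocol, session)
            n_cs = sum(1 for e in epochs if e[2].startswith("CS"))
            bouts = []
            for start, end, label in epochs:
                if label == "no_CS":
                    target = NO_CS_FREEZING + offset
                else:
                    i = int(label[2:]) - 1
                    frac = i / max(n_cs - 1, 1)
                    target = lvl0 + (lvl1 - lvl0) * frac + offset
                target += rng.normal(0.0, FREEZING_EPOCH_SD)
                target = float(np.clip(target, 0.0, 93.0))
                dur = (end - start) * target / 100.0
                if dur >= beh.MIN_BOUT_S:
                    bouts.append((start + 0.5, start + 0.5 + dur))
            trace = syn.simulate_movement_trace(bouts, sess.duration,
                                                sample_rate=20.0)
            score = beh.score_freezing(trace, epochs)
            blocks = beh.block_average(score)
            for label, pct in zip(blocks.labels, blocks.percent):
                rows.append({"subject": f"m{subj:02d}", "session": session,
                             "epoch": label, "percent_freezing": pct})
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig | dict) -> RunReport:
    if isinstance(config, dict):
        config = PipelineConfig.from_dict(config)
    root = np.random.SeedSequence(config.seed)
    s_proto, s_units, s_wf, s_beh, s_tag = [
        int(s.generate_state(1)[0] % (2 ** 31)) for s in root.spawn(5)]
    protocol = build_protocol(config.template, seed=s_proto)

    units = _make_units(config)
    trains = {}
    for k, u in enumerate(units):
        trains[u["unit_id"]] = syn.simulate_unit_spikes(
            u["phenotype"], protocol, config.state_schedule,
            seed=s_units + k, unit_id=u["unit_id"],
            sessions=list(config.sessions))

    # waveforms and per-channel cluster QC (two units share a channel)
    waveform_sets = {}
    for k, u in enumerate(units):
        tpl = _WAVEFORM_TEMPLATES[k % 2]
        waveform_sets[u["unit_id"]] = syn.simulate_waveforms(
            [tpl], 100, config.waveform_noise_sd, seed=s_wf + k)[0]
    qc_rows = []
    for k in range(0, len(units) - 1, 2):
        pair = [waveform_sets[units[k]["unit_id"]],
                waveform_sets[units[k + 1]["unit_id"]]]
        feats = qc.waveform_features(pair, n_components=3)
        qc_rows.append({"channel": k // 2,
                        "units": f"{units[k]['unit_id']}+{units[k+1]['unit_id']}",
                        "j3": qc.j3_statistic(feats),
                        "db": qc.davies_bouldin(feats)})
    qc_channels = pd.DataFrame(qc_rows)

    # exclusions, in order: duplicate -> refractory -> undefined baseline
    disposition = {u["unit_id"]: "classified" for u in units}
    ref_session = "extinction1"
    ref_trains = {uid: tr[ref_session] for uid, tr in trains.items()}
    ids = [u["unit_id"] for u in units]
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            a, b = ref_trains[ids[i]], ref_trains[ids[j]]
            if disposition[ids[i]] != "classified" \
                    or disposition[ids[j]] != "classified":
                continue
            flag, _ = qc.duplicate_units(a, b)
            if flag:
                drop = ids[i] if a.n_spikes <= b.n_spikes else ids[j]
                disposition[drop] = "excluded:duplicate"
    for uid in ids:
        if disposition[uid] != "classified":
            continue
        frac, _ = qc.refractory_check(ref_trains[uid])
        if frac is None or frac > config.refractory_max_fraction:
            disposition[uid] = "excluded:refractory"

    # PSTHs, reference-block z-scores and classification
    pips_ref = {s: pip_onsets(protocol, s) for s in config.sessions}
    blocks_ref = block_epochs(protocol, ref_session)
    n_per_cs = len(pip_onsets(protocol, ref_session, cs_indices=[0]))
    first_block = np.arange(len(blocks_ref[0].cs_indices) * n_per_cs)
    classifications = []
    zref_by_unit = {}
    for u in units:
        uid = u["unit_id"]
        if disposition[uid] != "classified":
            continue
        mat = ps.pip_psth(ref_trains[uid], pips_ref[ref_session])
        zsig = ps.zscore_block(mat, first_block,
                               scale=config.classification.zscore_scale)
        if not zsig.valid:
            disposition[uid] = "excluded:undefined_baseline"
            continue
        zref_by_unit[uid] = ps.zscore_block(mat, first_block, scale="sd")
        c = cls.classify_unit(zsig, u["region"], config.classification)
        epochs = {}
        if "habituation" in config.sessions:
            hab = ps.pip_psth(trains[uid]["habituation"],
                              pips_ref["habituation"])
            epochs["habituation"] = ps.zscore_block(
                hab, np.arange(min(first_block.size, hab.n_trials)))
        epochs["ext1_begin"] = zref_by_unit[uid]
        if "extinction2" in config.sessions:
            e2 = ps.pip_psth(trains[uid]["extinction2"],
                             pips_ref["extinction2"])
            last = [b for b in block_epochs(protocol, "extinction2")
                    if not b.partial][-1]
            idx = np.concatenate([np.arange(ci * n_per_cs, (ci + 1) * n_per_cs)
                                  for ci in last.cs_indices])
            epochs["ext2_end"] = ps.zscore_block(e2, idx)
        summaries = {}
        for name, zp in epochs.items():
            if zp.valid:
                bins = cls._response_bins(
                    zp, config.classification.response_window)
                summaries[name] = float(zp.z[bins].mean())
        classifications.append(cls.UnitClassification(
            uid, c.region, c.label, c.peak_z, c.peak_latency, summaries))

    class_table = cls.classification_table(classifications) \
        if classifications else pd.DataFrame(
            columns=["unit_id", "region", "label", "functional_class",
                     "peak_z", "peak_latency_s"])

    # confusion matrix on classified units
    true_by_id = {u["unit_id"]: u["true_class"] for u in units}
    conf = pd.crosstab(
        pd.Series([true_by_id[c.unit_id] for c in classifications],
                  name="true_class", dtype=object),
        pd.Series([c.functional_class for c in classifications],
                  name="assigned", dtype=object),
    ) if classifications else pd.DataFrame()

    # population z-PSTH per true class at the reference block
    pop_rows = []
    for cell_class in config.units_per_class:
        zps = [zref_by_unit[c.unit_id] for c in classifications
               if true_by_id[c.unit_id] == cell_class]
        if not zps:
            continue
        pop = ps.population_psth(zps)
        for t, m, se in zip(pop.bin_starts, pop.mean_z, pop.sem):
            pop_rows.append({"true_class": cell_class, "bin_start_s": t,
                             "mean_z": m, "sem": se, "n_units": pop.n_units})
    population = pd.DataFrame(pop_rows)

    # behaviour
    freezing = _simulate_freezing(protocol, config,
                                  np.random.default_rng(s_beh))
    if len(freezing):
        sub = freezing[freezing["epoch"].isin(
            ["CS_block1", "CS_block3"])].copy()
        sub["condition"] = sub["session"] + ":" + sub["epoch"]
        keep = ["habituation:CS_block1", "extinction1:CS_block1",
                "extinction2:CS_block3"]
        sub = sub[sub["condition"].isin(keep)]
        anova = beh.rm_anova(sub, "percent_freezing", "condition", "subject")
        posthoc = beh.bonferroni_posthoc(sub, "percent_freezing", "condition",
                                         "subject", "habituation:CS_block1")
        anova_df, posthoc_df = anova.effects, posthoc
    else:
        anova_df = pd.DataFrame()
        posthoc_df = pd.DataFrame()

    # phototagging of Arch-expressing units
    tag_rows = []
    pulses = pt.LightPulseTrain.standard()
    for k in range(config.n_tagged):
        train = syn.simulate_phototag_unit(15.0, 1.5, 0.02, pulses,
                                           seed=s_tag + k,
                                           unit_id=f"tag{k:02d}")
        wf = syn.simulate_waveforms([_WAVEFORM_TEMPLATES[0]] * 2, 50,
                                    config.waveform_noise_sd, seed=s_tag + k)
        res = pt.phototag_unit(train, pulses, wf[0], wf[1],
                               seed=s_tag + k)
        tag_rows.append({"unit_id": res.unit_id, "responsive": res.responsive,
                         "sign": res.sign, "latency_ms": res.latency_s * 1e3,
                         "magnitude_pct": res.magnitude_pct,
                         "p_value": res.p_value,
                         "waveform_r": res.waveform_r})
    phototag_df = pd.DataFrame(tag_rows)

    units_df = pd.DataFrame([
        {"unit_id": u["unit_id"], "true_class": u["true_class"],
         "region": u["region"], "disposition": disposition[u["unit_id"]]}
        for u in units])

    cfg_echo = asdict(config)
    cfg_echo["classification"] = asdict(config.classification)
    return RunReport(
        config=cfg_echo, seed=config.seed, version=_version(),
        units=units_df, classification=class_table, confusion=conf,
        qc_channels=qc_channels, phototag=phototag_df, freezing=freezing,
        freezing_anova=anova_df, freezing_posthoc=posthoc_df,
        population_psth=population)


def _version() -> str:
    from importlib.metadata import PackageNotFoundError, version
    try:
        return version("ceaphys")
    except PackageNotFoundError:
        return "unknown"
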