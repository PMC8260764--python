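"""Freezing scorer rules, the recovery cut-off, and the within-subject
statistics against hand-computed oracles."""

import numpy as np
import pandas as pd
import pytest

from ceaphys.behavior import (block_average, bonferroni_posthoc, cs_epochs,
                              freezing_cutoff_filter, paired_t, rm_anova,
                              score_freezing)
from ceaphys.core import MovementTrace
from ceaphys.protocol import BlockSpec, build_protocol
from ceaphys.synthetic import simulate_movement_trace


class TestScorer:
    def test_continuous_movement_scores_zero(self):
        tr = MovementTrace(10.0, np.ones(300, dtype=np.int8))
        assert score_freezing(tr, [(0.0, 30.0, "CS1")])["CS1"] == 0.0

    def test_fully_immobile_scores_hundred(self):
        tr = MovementTrace(10.0, np.zeros(300, dtype=np.int8))
        assert score_freezing(tr, [(0.0, 30.0, "CS1")])["CS1"] == 100.0

    def test_six_second_bout_in_thirty_seconds_is_twenty_percent(self):
        tr = simulate_movement_trace([(4.0, 10.0)], 30.0, 10.0)
        assert score_freezing(tr, [(0.0, 30.0, "CS1")])["CS1"] \
            == pytest.approx(20.0)

    def test_sub_threshold_bout_ignored(self):
        tr = simulate_movement_trace([(4.0, 5.9)], 30.0, 10.0)
        assert score_freezing(tr, [(0.0, 30.0, "CS1")])["CS1"] == 0.0

    def test_exactly_two_second_bout_counts_fully(self):
        tr = simulate_movement_trace([(4.0, 6.0)], 30.0, 10.0)
        assert score_freezing(tr, [(0.0, 30.0, "CS1")])["CS1"] \
            == pytest.approx(100.0 * 2.0 / 30.0)

    def test_sample_rate_refinement_invariance(self):
        bouts = [(3.0, 8.5), (12.0, 13.0), (20.0, 27.0)]
        scores = [score_freezing(simulate_movement_trace(bouts, 30.0, fs),
                                 [(0.0, 30.0, "e")])["e"]
                  for fs in (10.0, 100.0)]
        assert scores[0] == pytest.approx(scores[1])

    def test_generator_scorer_round_trip(self, rng):
        """Bout schedules with >=2-s bouts are scored back exactly."""
        epoch = (0.0, 60.0, "e")
        t = 0.0
        bouts = []
        while t < 50.0:
            start = t + rng.uniform(1.0, 4.0)
            dur = rng.uniform(2.0, 6.0)
            bouts.append((round(start, 1), round(min(start + dur, 59.0), 1)))
            t = bouts[-1][1]
        tr = simulate_movement_trace(bouts, 60.0, 10.0)
        expected = 100.0 * sum(b - a for a, b in bouts if b - a >= 2.0) / 60.0
        assert score_freezing(tr, [epoch])["e"] == pytest.approx(expected)

    def test_zero_length_epoch_rejected(self):
        tr = MovementTrace(10.0, np.ones(100, dtype=np.int8))
        with pytest.raises(ValueError):
            score_freezing(tr, [(2.0, 2.0, "bad")])

    def test_protocol_epochs_and_block_average(self):
        proto = build_protocol("standard", seed=3)
        epochs = cs_epochs(proto, "extinction1")
        assert epochs[0][2] == "no_CS"
        assert sum(1 for e in epochs if e[2].startswith("CS")) == 12
        score = score_freezing(
            MovementTrace(10.0, np.zeros(
                int(proto.session("extinction1").duration * 10),
                dtype=np.int8)), epochs)
        blocks = block_average(score, BlockSpec(4))
        assert "CS_block3" in blocks.labels
        assert blocks["CS_block1"] == 100.0


class TestCutoff:
    def test_boundary_and_typical_cases(self):
        scores = {"m1": 32.5, "m2": 75.0, "m3": 50.0, "m4": 49.9}
        assert freezing_cutoff_filter(scores) == ["m1", "m4"]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            freezing_cutoff_filter({})


def long_table(values):
    """values: dict condition -> per-subject list."""
    rows = []
    for cond, vals in values.items():
        for i, v in enumerate(vals):
            rows.append({"subject": f"s{i}", "cond": cond, "v": float(v)})
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_f_equals_squared_paired_t(self):
        df = long_table({"a": [10, 11, 9], "b": [12, 15, 12]})
        res = rm_anova(df, "v", "cond", "subject")
        eff = res.effect("cond")
        assert eff["F"] == pytest.approx(27.0)
        assert (eff["df1"], eff["df2"]) == (1, 2)
        t, tdf, p = paired_t([12, 15, 12], [10, 11, 9])
        assert t ** 2 == pytest.approx(eff["F"])
        assert p == pytest.approx(eff["p"])

    def test_equal_condition_means_give_zero_f(self):
        df = long_table({"a": [1, 2, 3], "b": [2, 1, 3]})
        assert rm_anova(df, "v", "cond", "subject").effect("cond")["F"] \
            == pytest.approx(0.0)

    def test_sum_of_squares_decomposition(self, rng):
        """One-way within-subject F recomputed from the partitioned sums
        of squares matches the library fit."""
        n_sub, n_cond = 8, 4
        x = rng.normal(size=(n_sub, n_cond))
        df = long_table({f"c{j}": x[:, j] for j in range(n_cond)})
        eff = rm_anova(df, "v", "cond", "subject").effect("cond")
        grand = x.mean()
        ss_cond = n_sub * ((x.mean(0) - grand) ** 2).sum()
        ss_sub = n_cond * ((x.mean(1) - grand) ** 2).sum()
        ss_tot = ((x - grand) ** 2).sum()
        ss_err = ss_tot - ss_cond - ss_sub
        f_manual = (ss_cond / (n_cond - 1)) \
            / (ss_err / ((n_sub - 1) * (n_cond - 1)))
        assert eff["F"] == pytest.approx(f_manual)
        assert (eff["df1"], eff["df2"]) == (n_cond - 1,
                                            (n_sub - 1) * (n_cond - 1))

    def test_two_way_reports_interaction(self, rng):
        rows = []
        for s in range(6):
            for a in ("light", "sham"):
                for b in ("cs1", "cs2", "cs3"):
                    rows.append({"subject": f"s{s}", "A": a, "B": b,
                                 "v": rng.normal()})
        res = rm_anova(pd.DataFrame(rows), "v", ["A", "B"], "subject")
        assert set(res.effects["factor"]) == {"A", "B", "A * B"}

    def test_incomplete_design_rejected(self):
        df = long_table({"a": [1, 2, 3], "b": [2, 1, 3]}).iloc[:-1]
        with pytest.raises(ValueError):
            rm_anova(df, "v", "cond", "subject")

    def test_single_subject_rejected(self):
        df = long_table({"a": [1], "b": [2]})
        with pytest.raises(ValueError):
            rm_anova(df, "v", "cond", "subject")


class TestPosthocAndPairedT:
    def test_adjustment_arithmetic(self, rng):
        conds = {f"c{j}": rng.normal(size=6) for j in range(4)}
        conds["ref"] = rng.normal(size=6)
        table = bonferroni_posthoc(long_table(conds), "v", "cond",
                                   "subject", "ref")
        assert len(table) == 4
        assert np.allclose(table["p_adj"],
                           np.minimum(1.0, 4 * table["p_raw"]))

    def test_single_comparison_unadjusted(self, rng):
        conds = {"a": rng.normal(size=5), "ref": rng.normal(size=5)}
        table = bonferroni_posthoc(long_table(conds), "v", "cond",
                                   "subject", "ref")
        assert table["p_adj"].iloc[0] == pytest.approx(
            table["p_raw"].iloc[0])

    def test_adjusted_p_capped_at_one(self):
        conds = {"a": [1.0, 2.0, 3.0, 2.5], "b": [1.1, 1.9, 3.1, 2.4],
                 "ref": [1.0, 2.1, 2.9, 2.6]}
        table = bonferroni_posthoc(long_table(conds), "v", "cond",
                                   "subject", "ref")
        assert (table["p_adj"] <= 1.0).all()

    def test_paired_t_hand_example(self):
        t, df, p = paired_t([12, 15, 12], [10, 11, 9])
        assert t == pytest.approx(5.196, abs=1e-3)
        assert df == 2

    def test_identical_vectors(self):
        t, df, p = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, p) == (0.0, 1.0)

    def test_constant_nonzero_differences_rejected(self):
        with pytest.raises(ValueError):
            paired_t([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
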