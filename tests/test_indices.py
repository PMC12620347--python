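"""Stroop IF index, response proportions, AOI metrics, effect sizes, FDR."""

import numpy as np
import pandas as pd
import pytest

from scrmpt import (
    aoi_metrics,
    bh_adjust,
    group_effect_size,
    inhibition_index,
    response_proportions,
)


def stroop_frame(rt_cons, rt_incons, correct=None):
    n1, n2 = len(rt_cons), len(rt_incons)
    correct = correct if correct is not None else [1] * (n1 + n2)
    return pd.DataFrame(
        {
            "condition": ["consistent"] * n1 + ["inconsistent"] * n2,
            "rt_ms": list(rt_cons) + list(rt_incons),
            "correct": correct,
        }
    )


class TestInhibitionIndex:
    def test_no_interference_cost_scores_two(self):
        s = inhibition_index(stroop_frame([800, 800], [800, 800]))
        assert s.IF == pytest.approx(2.0)

    def test_worked_example(self):
        # acc .9, cons 800 ms, incons 1000 ms -> .9 * (2 - .25) = 1.575
        trials = stroop_frame(
            [800] * 10, [1000] * 10, correct=[1] * 9 + [0] + [1] * 9 + [0]
        )
        # keep RT means at 800/1000 regardless of which trials are correct
        s = inhibition_index(trials)
        assert s.acc == pytest.approx(0.9)
        assert s.IF == pytest.approx(0.9 * (2 - 0.25))

    def test_zero_accuracy_zeroes_the_index(self):
        trials = stroop_frame([500, 600], [900, 950], correct=[0, 0, 0, 0])
        assert inhibition_index(trials).IF == 0.0

    def test_rt_means_use_correct_trials_only(self):
        trials = stroop_frame([800, 4000], [1000, 5000], correct=[1, 0, 1, 0])
        s = inhibition_index(trials)
        assert s.rt_consistent == 800 and s.rt_inconsistent == 1000
        all_tr = inhibition_index(trials, rt_correct_only=False)
        assert all_tr.rt_consistent == 2400

    def test_missing_condition_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            inhibition_index(stroop_frame([800], []))

    def test_invariant_to_common_rt_rescaling(self):
        rng = np.random.default_rng(0)
        cons = rng.uniform(500, 900, 20)
        incons = rng.uniform(600, 1100, 20)
        base = inhibition_index(stroop_frame(cons, incons)).IF
        scaled = inhibition_index(stroop_frame(cons * 3.7, incons * 3.7)).IF
        assert scaled == pytest.approx(base, rel=1e-12)

    def test_nonpositive_rt_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            inhibition_index(stroop_frame([800, -5], [900]))


def trials_frame(rows):
    return pd.DataFrame(
        rows, columns=["participant_id", "group", "condition", "probe", "response"]
    )


class TestResponseProportions:
    def test_perfect_responder(self):
        rows = [
            ("p1", "g", "c", probe, probe)
            for probe in ("intact", "related", "unrelated")
            for _ in range(5)
        ]
        table = response_proportions(trials_frame(rows))
        assert table["accuracy"].iloc[0] == 1.0
        assert table.set_index("probe").loc["related", "R_I"] == 0.0

    def test_always_intact_responder(self):
        rows = [
            ("p1", "g", "c", probe, "intact")
            for probe in ("intact", "intact", "related", "unrelated")
        ]
        table = response_proportions(trials_frame(rows))
        assert table["R_I"].iloc[0] == 1.0
        assert table["accuracy"].iloc[0] == pytest.approx(0.5)  # 2 intact / 4

    def test_rows_sum_to_one_and_missing_probe_is_nan(self):
        rows = [("p1", "g", "c", "intact", "related")] * 3
        table = response_proportions(trials_frame(rows)).set_index("probe")
        probs = table.loc["intact", ["p_intact", "p_related", "p_unrelated"]]
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.isnan(table.loc["related", "p_intact"])


class TestAOIMetrics:
    AOIS = {"A": (0, 0, 100, 100), "B": (200, 0, 300, 100)}

    def fixations(self, rows):
        return pd.DataFrame(rows, columns=["x", "y", "duration_ms"])

    def test_empty_input_all_zero(self):
        out = aoi_metrics(self.fixations([]), self.AOIS).set_index("aoi")
        assert (out[["FD", "FF", "FD_P", "FF_P"]] == 0).all().all()

    def test_sub_threshold_fixation_excluded(self):
        out = aoi_metrics(self.fixations([(50, 50, 99.0)]), self.AOIS)
        assert (out[["FD", "FF"]] == 0).all().all()

    def test_threshold_boundary_retained(self):
        out = aoi_metrics(self.fixations([(50, 50, 100.0)]), self.AOIS).set_index("aoi")
        assert out.loc["A", "FD"] == 100.0

    def test_outside_time_in_denominator(self):
        fx = self.fixations([(50, 50, 200.0), (250, 50, 200.0), (500, 500, 100.0)])
        out = aoi_metrics(fx, self.AOIS).set_index("aoi")
        assert out.loc["A", "FD_P"] == pytest.approx(0.4)
        assert out.loc["B", "FF_P"] == pytest.approx(1 / 3)

    def test_edge_point_counts_as_inside(self):
        out = aoi_metrics(self.fixations([(100, 100, 150.0)]), self.AOIS).set_index("aoi")
        assert out.loc["A", "FF"] == 1

    def test_overlapping_aois_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            aoi_metrics(self.fixations([]), {"A": (0, 0, 100, 100), "B": (50, 50, 150, 150)})

    def test_order_invariance_and_additivity(self):
        rng = np.random.default_rng(1)
        rows = [
            (rng.uniform(0, 400), rng.uniform(0, 200), rng.uniform(80, 400))
            for _ in range(60)
        ]
        base = aoi_metrics(self.fixations(rows), self.AOIS)
        shuffled = aoi_metrics(
            self.fixations([rows[i] for i in rng.permutation(60)]), self.AOIS
        )
        pd.testing.assert_frame_equal(base, shuffled)
        first = aoi_metrics(self.fixations(rows[:30]), self.AOIS)
        second = aoi_metrics(self.fixations(rows[30:]), self.AOIS)
        assert np.allclose(base["FD"], first["FD"] + second["FD"])
        assert np.allclose(base["FF"], first["FF"] + second["FF"])


class TestEffectSizeAndFDR:
    def test_equal_means_zero(self):
        assert group_effect_size(5, 1, 10, 5, 2, 12) == (0.0, 0.0)

    def test_interfering_word_duration_row(self):
        d, t = group_effect_size(275.92, 306.82, 30, 495.91, 416.45, 29)
        assert round(d, 2) == -0.60
        assert round(t, 2) == -2.32  # pooled-variance t near the reported -2.30

    def test_unit_pooled_sd(self):
        d, _ = group_effect_size(0, 1, 2, 1, 1, 2)
        assert d == pytest.approx(-1.0)

    def test_zero_pooled_sd_signals_infinity(self):
        d, t = group_effect_size(1, 0, 5, 0, 0, 5)
        assert np.isinf(d) and d > 0

    def test_bh_single_p_unchanged(self):
        assert bh_adjust([0.037])[0] == pytest.approx(0.037)

    def test_bh_step_up_hand_case(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_bh_equal_ps_unchanged_and_order_preserved(self):
        out = bh_adjust([0.2, 0.2, 0.2])
        assert np.allclose(out, 0.2)
        mixed = bh_adjust([0.04, 0.001, 0.9])
        assert mixed[1] < mixed[0] < mixed[2]

    def test_bh_monotone_in_order_statistics_and_bounded(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=40)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        assert np.all(adj <= 1.0)

    def test_bh_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])
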