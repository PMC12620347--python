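"""Synthetic generators: reproducibility, schema validity, calibration."""

import numpy as np
import pandas as pd
import pytest

from scrmpt import (
    MPT_PRESETS,
    category_probabilities,
    generate_eye_indicators,
    generate_mpt_dataset,
    generate_path_dataset,
    generate_stroop_trials,
    inhibition_index_table,
)
from scrmpt.indices import aoi_metrics
from scrmpt.io import aggregate_trials, validate_trials
from scrmpt.synthetic import DEFAULT_AOIS
from scrmpt.tree import MPTParameters


class TestSeedReproducibility:
    def test_mpt_generator(self):
        a = generate_mpt_dataset("older_gist", n_participants=8, seed=3)
        b = generate_mpt_dataset("older_gist", n_participants=8, seed=3)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_other_generators(self):
        s1, _ = generate_stroop_trials(n_participants=4, seed=5)
        s2, _ = generate_stroop_trials(n_participants=4, seed=5)
        pd.testing.assert_frame_equal(s1, s2)
        e1, _ = generate_eye_indicators(n_per_group=(6, 6), seed=5)
        e2, _ = generate_eye_indicators(n_per_group=(6, 6), seed=5)
        pd.testing.assert_frame_equal(e1, e2)
        p1, _ = generate_path_dataset(n=20, seed=5)
        p2, _ = generate_path_dataset(n=20, seed=5)
        pd.testing.assert_frame_equal(p1, p2)


class TestMPTGenerator:
    def test_output_passes_downstream_validation(self):
        trials, meta, truth = generate_mpt_dataset("older_gist", n_participants=6, seed=1)
        validate_trials(trials)
        counts = aggregate_trials(trials)
        assert len(counts) == 6
        arr = counts.filter(like="n_").to_numpy().reshape(-1, 3, 3)
        assert np.all(arr.sum(axis=2) == [15, 18, 15])
        assert set(meta.columns) == {"participant_id", "group", "education_years"}
        assert truth.params["group_probabilities"]["Vi"] == MPT_PRESETS["older_gist"]["Vi"]

    def test_two_conditions_give_paper_totals(self):
        per_participant = []
        for cond in ("gist", "nongist"):
            trials, _, _ = generate_mpt_dataset(
                "older_gist", n_participants=1, seed=2, condition=cond
            )
            per_participant.append(trials.groupby("probe").size())
        total = per_participant[0] + per_participant[1]
        assert total["intact"] == 30 and total["related"] == 36 and total["unrelated"] == 30

    def test_zero_heterogeneity_matches_closed_form(self):
        probs = MPT_PRESETS["older_gist"]
        trials, _, _ = generate_mpt_dataset(
            probs, n_participants=1, trials_per_probe=(40000, 40000, 40000),
            seed=4, re_sd=0.0, re_corr=0.0,
        )
        params = MPTParameters.constrained(
            vi=probs["Vi"], vr=probs["Vr"], g=probs["G"], a=probs["a"],
            ab=probs["ab"], b=probs["b"],
        )
        for probe in ("intact", "related", "unrelated"):
            sub = trials[trials["probe"] == probe]
            emp = sub["response"].value_counts(normalize=True)
            expected = category_probabilities(params, probe)
            for j, resp in enumerate(("intact", "related", "unrelated")):
                se = np.sqrt(expected[j] * (1 - expected[j]) / len(sub))
                assert abs(emp.get(resp, 0.0) - expected[j]) < 4 * se + 1e-9

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError, match="unknown preset"):
            generate_mpt_dataset("no_such_cell", seed=0)


class TestStroopGenerator:
    def test_default_trial_counts(self):
        trials, _ = generate_stroop_trials(n_participants=2, seed=0)
        per = trials.groupby(["participant_id", "condition"]).size()
        assert (per == 40).all()

    def test_zero_cost_perfect_accuracy_approaches_two(self):
        trials, truth = generate_stroop_trials(
            n_participants=3, n_consistent=3000, n_inconsistent=3000,
            accuracy=1.0, cost_frac=0.0, accuracy_sd=0.0, cost_sd=0.0, seed=1,
        )
        table = inhibition_index_table(trials)
        assert truth.params["implied_IF"] == 2.0
        assert np.allclose(table["IF"], 2.0, atol=0.05)

    def test_quarter_cost_gives_expected_if(self):
        trials, truth = generate_stroop_trials(
            n_participants=4, n_consistent=4000, n_inconsistent=4000,
            accuracy=0.9, cost_frac=0.25, accuracy_sd=0.0, cost_sd=0.0, seed=2,
        )
        assert truth.params["implied_IF"] == pytest.approx(1.575)
        table = inhibition_index_table(trials)
        assert table["IF"].mean() == pytest.approx(1.575, abs=0.03)


class TestEyeGenerator:
    def test_indicator_correlations_follow_loadings(self):
        lam = (0.96, 0.98, 0.99, 0.99)
        df, _ = generate_eye_indicators(
            n_per_group=(20000, 20000), loadings=lam, group_to_latent=0.0, seed=3
        )
        r = np.corrcoef(df[["FD", "FF"]].to_numpy().T)[0, 1]
        assert r == pytest.approx(lam[0] * lam[2], abs=0.02)

    def test_invalid_loadings_rejected(self):
        with pytest.raises(ValueError, match="loadings"):
            generate_eye_indicators(loadings=(1.2, 0.9, 0.9, 0.9), seed=0)

    def test_fixation_streams_reproduce_indicators(self):
        df, streams, _ = generate_eye_indicators(
            n_per_group=(6, 6), units="natural", fixation_streams=True, seed=4
        )
        for pid, sub in streams.groupby("participant_id"):
            row = df.set_index("participant_id").loc[pid]
            out = aoi_metrics(sub, DEFAULT_AOIS).set_index("aoi").loc["interfering_word"]
            expected_fd = max(row["FD"], 100.0 * max(round(row["FF"]), 1))
            assert out["FD"] == pytest.approx(expected_fd, rel=1e-9)
            assert out["FF"] == max(round(row["FF"]), 1)
            if expected_fd == row["FD"]:
                assert out["FD_P"] == pytest.approx(row["FD_P"], rel=0.02)


class TestPathGenerator:
    def test_null_truth_gives_independent_variables(self):
        null = {k: 0.0 for k in ("a1", "a2", "d21", "b1", "b2", "c_prime")}
        df, _ = generate_path_dataset(truth=null, n=20000, seed=5)
        corr = df.corr().to_numpy()
        off = corr[np.triu_indices(4, 1)]
        assert np.all(np.abs(off) < 0.03)

    def test_variances_near_one(self):
        df, _ = generate_path_dataset(n=50000, seed=6)
        assert np.allclose(df.var(ddof=1), 1.0, atol=0.03)

    def test_truth_records_indirect_products(self):
        _, truth = generate_path_dataset(n=10, seed=7)
        t = truth.params
        assert t["indirect"]["a1*d21*b2"] == pytest.approx(
            t["a1"] * t["d21"] * t["b2"]
        )

    def test_binary_x_mode_emits_group_codes(self):
        df, _ = generate_path_dataset(n=40, seed=8, binary_x=True)
        assert set(df["group"].unique()) == {1, 2}

    def test_overdetermined_coefficients_rejected(self):
        bad = {"a1": 0.9, "a2": 0.9, "d21": 0.9, "b1": 0.1, "b2": 0.1, "c_prime": 0.1}
        with pytest.raises(ValueError, match="variance"):
            generate_path_dataset(truth=bad, n=10, seed=9)
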