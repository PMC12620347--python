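"""Tree closed forms, path enumeration, simulation and likelihood."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scrmpt import (
    CountTable,
    ModelVariant,
    MPTParameters,
    category_probabilities,
    enumerate_tree_paths,
    log_likelihood,
    simulate_counts,
)

unit = st.floats(0.0, 1.0, allow_nan=False)


def params_from(vals, constraint=False):
    vi, vr, gi, gr, a, ab, b = vals
    if constraint:
        gr = gi
    return MPTParameters(vi=vi, vr=vr, gi=gi, gr=gr, a=a, ab=ab, b=b,
                         constraint_gi_eq_gr=constraint)


EXAMPLE = MPTParameters(vi=0.5, vr=0.2, gi=0.6, gr=0.6, a=0.4, ab=0.3, b=0.1)


class TestClosedForms:
    def test_certain_verbatim_forces_intact(self):
        p = MPTParameters(vi=1.0, vr=0.2, gi=0.6, gr=0.3, a=0.4, ab=0.9, b=0.5)
        assert np.allclose(category_probabilities(p, "intact"), [1, 0, 0])

    @pytest.mark.parametrize("probe", ["intact", "related", "unrelated"])
    def test_no_retrieval_no_guessing_always_unrelated(self, probe):
        p = MPTParameters(vi=0, vr=0, gi=0, gr=0, a=0, ab=0, b=0)
        assert np.allclose(category_probabilities(p, probe), [0, 0, 1])

    def test_worked_intact_example(self):
        # frozen from the path-enumeration oracle at these parameter values
        probs = category_probabilities(EXAMPLE, "intact")
        assert np.allclose(probs, [0.626, 0.194, 0.180], atol=1e-12)

    @pytest.mark.parametrize("probe", ["intact", "related", "unrelated"])
    @pytest.mark.parametrize("variant", ["greene", "original"])
    def test_matches_enumeration_oracle(self, probe, variant):
        rng = np.random.default_rng(42)
        for _ in range(250):
            vals = rng.uniform(size=7)
            if variant == "original":
                vals[5] = vals[4]  # ab aliased to a
            p = params_from(vals)
            closed = category_probabilities(p, probe, variant)
            paths = enumerate_tree_paths(p, probe, variant)
            assert abs(sum(t.probability for t in paths) - 1.0) < 1e-12
            by_resp = np.zeros(3)
            order = ["intact", "related", "unrelated"]
            for t in paths:
                by_resp[order.index(t.response.value)] += t.probability
            assert np.allclose(closed, by_resp, atol=1e-12)
            assert abs(closed.sum() - 1.0) < 1e-12

    def test_variant_equivalence_when_ab_equals_a(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            vals = rng.uniform(size=7)
            vals[5] = vals[4]
            p = params_from(vals)
            for probe in ("intact", "related", "unrelated"):
                assert np.allclose(
                    category_probabilities(p, probe, "greene"),
                    category_probabilities(p, probe, "original"),
                )

    @given(
        vi=st.floats(0, 0.99), dvi=st.floats(0.0, 0.5), gi=unit, a=unit,
        ab=unit, b=unit,
    )
    @settings(max_examples=200, derandomize=True)
    def test_intact_hit_rate_monotone_in_verbatim(self, vi, dvi, gi, a, ab, b):
        vi2 = min(vi + dvi, 1.0)
        lo = MPTParameters(vi=vi, vr=0, gi=gi, gr=0, a=a, ab=ab, b=b)
        hi = MPTParameters(vi=vi2, vr=0, gi=gi, gr=0, a=a, ab=ab, b=b)
        assert (
            category_probabilities(hi, "intact")[0]
            >= category_probabilities(lo, "intact")[0] - 1e-12
        )

    def test_parameter_outside_unit_interval_names_offender(self):
        with pytest.raises(ValueError, match="vr"):
            MPTParameters(vi=0.5, vr=1.2, gi=0.5, gr=0.5, a=0.5, ab=0.5, b=0.5)

    def test_original_variant_rejects_conflicting_ab(self):
        p = MPTParameters(vi=0.5, vr=0.2, gi=0.6, gr=0.6, a=0.4, ab=0.3, b=0.1)
        with pytest.raises(ValueError, match="alias"):
            category_probabilities(p, "intact", "original")


class TestEnumeration:
    def test_leaf_counts(self):
        # intact and related subtrees have 6 leaves (3 x intact, 2 x related,
        # 1 x unrelated); the unrelated subtree has only the guessing branches
        assert len(enumerate_tree_paths(EXAMPLE, "intact")) == 6
        assert len(enumerate_tree_paths(EXAMPLE, "related")) == 6
        assert len(enumerate_tree_paths(EXAMPLE, "unrelated")) == 3

    def test_path_probability_is_branch_product(self):
        for t in enumerate_tree_paths(EXAMPLE, "intact"):
            lookup = {
                "Vi": 0.5, "1-Vi": 0.5, "Gi": 0.6, "1-Gi": 0.4,
                "a": 0.4, "1-a": 0.6, "b": 0.1, "1-b": 0.9,
                "ab": 0.3, "1-ab": 0.7,
            }
            assert t.probability == pytest.approx(
                np.prod([lookup[br] for br in t.branches]), abs=1e-15
            )


class TestSimulation:
    def test_zero_totals_give_empty_table(self):
        tab = simulate_counts(EXAMPLE, (0, 0, 0), seed=0)
        assert tab.counts.sum() == 0

    def test_degenerate_category(self):
        p = MPTParameters(vi=1.0, vr=0.2, gi=0.6, gr=0.6, a=0.4, ab=0.3, b=0.1)
        tab = simulate_counts(p, (100, 0, 0), seed=0)
        assert tab.counts[0, 0] == 100

    def test_empirical_proportions_match_closed_form(self):
        n = 100_000
        tab = simulate_counts(EXAMPLE, (n, 0, 0), seed=123)
        props = tab.counts[0] / n
        expected = category_probabilities(EXAMPLE, "intact")
        se = np.sqrt(expected * (1 - expected) / n)
        assert np.all(np.abs(props - expected) < 3 * se + 1e-9)

    def test_seed_reproducibility(self):
        a = simulate_counts(EXAMPLE, (50, 60, 50), seed=9)
        b = simulate_counts(EXAMPLE, (50, 60, 50), seed=9)
        assert np.array_equal(a.counts, b.counts)

    def test_negative_totals_rejected(self):
        with pytest.raises(ValueError, match="nonneg"):
            simulate_counts(EXAMPLE, (10, -1, 10), seed=0)


class TestLogLikelihood:
    def test_empty_table_is_zero(self):
        assert log_likelihood(EXAMPLE, CountTable()) == 0.0

    def test_single_trial_hand_product(self):
        # one intact probe answered "unrelated": (1-Vi)(1-Gi)(1-b)
        p = MPTParameters(vi=0.5, vr=0, gi=0.4, gr=0.4, a=0, ab=0, b=0.2)
        counts = np.zeros((3, 3), dtype=int)
        counts[0, 2] = 1
        assert log_likelihood(p, CountTable(counts)) == pytest.approx(
            np.log(0.5 * 0.6 * 0.8)
        )

    def test_definition_cross_check(self):
        tab = simulate_counts(EXAMPLE, (30, 36, 30), seed=4)
        manual = 0.0
        for i, probe in enumerate(("intact", "related", "unrelated")):
            probs = category_probabilities(EXAMPLE, probe)
            manual += float(np.sum(tab.counts[i] * np.log(probs)))
        assert log_likelihood(EXAMPLE, tab) == pytest.approx(manual, abs=1e-10)

    def test_impossible_cell_gives_minus_inf(self):
        p = MPTParameters(vi=1.0, vr=0, gi=0, gr=0, a=0, ab=0, b=0)
        counts = np.zeros((3, 3), dtype=int)
        counts[0, 1] = 1  # "related" response has probability 0 under vi=1,b=0
        assert log_likelihood(p, CountTable(counts)) == -np.inf


class TestCountTable:
    def test_row_totals(self):
        tab = CountTable(np.arange(9).reshape(3, 3))
        assert np.array_equal(tab.totals, [3, 12, 21])

    def test_rejects_negative_and_bad_shape(self):
        with pytest.raises(ValueError):
            CountTable(-np.ones((3, 3), dtype=int))
        with pytest.raises(ValueError):
            CountTable(np.zeros((2, 3), dtype=int))

    def test_from_responses_roundtrip(self):
        tab = CountTable.from_responses(
            ["intact", "intact", "related"], ["intact", "related", "unrelated"]
        )
        assert tab.counts[0, 0] == 1 and tab.counts[0, 1] == 1
        assert tab.counts[1, 2] == 1
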