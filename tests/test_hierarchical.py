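"""Hierarchical Bayesian fit, R-hat, posterior predictive checks, differences."""

import numpy as np
import pandas as pd
import pytest

from scrmpt import (
    HierarchicalMPT,
    condition_difference,
    generate_mpt_dataset,
    posterior_predictive_p,
    rhat,
    split_rhat,
)
from scrmpt.io import aggregate_trials


class TestSplitRhat:
    def test_iid_chains_near_one(self):
        rng = np.random.default_rng(0)
        chains = rng.normal(size=(4, 1000))
        assert split_rhat(chains) < 1.01

    def test_separated_chains_blow_up(self):
        rng = np.random.default_rng(1)
        chains = np.stack([rng.normal(0, 1, 500), rng.normal(10, 1, 500)])
        assert split_rhat(chains) > 1.1

    def test_duplicated_chain_split_in_half(self):
        rng = np.random.default_rng(2)
        one = rng.normal(size=600)
        assert split_rhat(np.stack([one, one])) == pytest.approx(1.0, abs=0.05)

    def test_zero_within_variance_is_undefined(self):
        assert np.isnan(split_rhat(np.ones((2, 10))))

    def test_too_few_chains_or_draws_rejected(self):
        with pytest.raises(ValueError):
            split_rhat(np.zeros((1, 100)))
        with pytest.raises(ValueError):
            split_rhat(np.zeros((2, 3)))

    def test_agrees_with_arviz_split_estimator(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(3)
        for scale in (1.0, 3.0):
            chains = np.cumsum(rng.normal(size=(4, 400)), axis=1) / scale
            ours = split_rhat(chains)
            theirs = float(az.rhat(chains[None].squeeze(0), method="split"))
            assert ours == pytest.approx(theirs, rel=1e-6)

    def test_dict_and_array_dispatch(self):
        rng = np.random.default_rng(4)
        arr = rng.normal(size=(2, 100, 3))
        out = rhat(arr)
        assert set(out) == {0, 1, 2}
        out2 = rhat({"a": arr[:, :, 0]})
        assert set(out2) == {"a"}


@pytest.fixture(scope="module")
def small_fit():
    trials, meta, truth = generate_mpt_dataset(
        "older_gist", n_participants=15, seed=51
    )
    counts = aggregate_trials(trials)
    fit = HierarchicalMPT(
        n_chains=2, n_warmup=250, n_draws=250, random_state=7
    ).fit(counts, meta)
    return fit, counts, truth


class TestHierarchicalFit:
    def test_summary_on_probability_scale(self, small_fit):
        fit, _, _ = small_fit
        s = fit.summary_
        assert list(s["parameter"]) == ["Vi", "Vr", "G", "a", "ab", "b"]
        assert ((s["mean"] >= 0) & (s["mean"] <= 1)).all()
        assert (s["lower"] <= s["mean"]).all() and (s["mean"] <= s["upper"]).all()

    def test_rhat_reported_for_group_level_quantities(self, small_fit):
        fit, _, _ = small_fit
        assert {"mu[Vi]", "sd[Vi]", "gamma[Vi]"} <= set(fit.rhat_)
        assert all(v >= 1.0 - 1e-9 or np.isnan(v) for v in fit.rhat_.values())

    def test_deterministic_under_fixed_seed(self, small_fit):
        fit, counts, _ = small_fit
        trials, meta, _ = generate_mpt_dataset("older_gist", n_participants=15, seed=51)
        refit = HierarchicalMPT(
            n_chains=2, n_warmup=250, n_draws=250, random_state=7
        ).fit(aggregate_trials(trials), meta)
        assert np.array_equal(fit.mu_draws_, refit.mu_draws_)

    def test_covariate_disabled_with_warning_when_missing(self, small_fit):
        _, counts, _ = small_fit
        with pytest.warns(UserWarning, match="covariate"):
            fit = HierarchicalMPT(
                n_chains=2, n_warmup=50, n_draws=50, random_state=1
            ).fit(counts, metadata=None)
        assert np.all(fit.gamma_draws_ == 0)

    def test_requires_seed_and_enough_participants(self):
        trials, meta, _ = generate_mpt_dataset("older_gist", n_participants=4, seed=5)
        counts = aggregate_trials(trials)
        with pytest.raises(ValueError, match="participants"):
            HierarchicalMPT(random_state=1, n_warmup=10, n_draws=10).fit(counts, meta)
        with pytest.raises(ValueError, match="seed"):
            HierarchicalMPT(random_state=None).fit(counts, meta)

    def test_multiple_conditions_rejected(self, small_fit):
        _, counts, _ = small_fit
        doubled = pd.concat(
            [counts, counts.assign(condition="nongist")], ignore_index=True
        )
        with pytest.raises(ValueError, match="one group x condition"):
            HierarchicalMPT(random_state=1).fit(doubled)


class TestPosteriorPredictive:
    def test_self_consistent_data_not_rejected(self, small_fit):
        fit, _, _ = small_fit
        p = posterior_predictive_p(fit)
        assert 0.01 < p < 0.99

    def test_gross_mismatch_detected(self, small_fit):
        fit, counts, _ = small_fit
        # every response "unrelated": incompatible with the fitted posterior
        bad = fit.counts_.copy()
        totals = bad.sum(axis=2)
        bad[:] = 0
        bad[:, :, 2] = totals
        assert posterior_predictive_p(fit, bad) < 0.05

    def test_p_in_unit_interval_and_shape_checked(self, small_fit):
        fit, _, _ = small_fit
        with pytest.raises(ValueError, match="shape"):
            posterior_predictive_p(fit, fit.counts_[:3])


class TestConditionDifference:
    def test_identity_gives_zero_differences(self, small_fit):
        fit, _, _ = small_fit
        diff = condition_difference(fit, fit, pairing="self")
        assert np.allclose(diff["mean"], 0)
        assert not diff["credible"].any()

    def test_detects_generated_gist_shift(self):
        # shared-G difference .78 vs .66 at modest size: credibly positive
        fits = []
        for g, seed in ((0.78, 61), (0.66, 62)):
            truth = {"Vi": 0.55, "Vr": 0.07, "G": g, "a": 0.5, "ab": 0.14, "b": 0.09}
            trials, meta, _ = generate_mpt_dataset(truth, n_participants=30, seed=seed)
            fits.append(
                HierarchicalMPT(
                    n_chains=2, n_warmup=300, n_draws=300, random_state=8
                ).fit(aggregate_trials(trials), meta)
            )
        diff = condition_difference(fits[0], fits[1], pairing="gist-nongist")
        row = diff.set_index("parameter").loc["G"]
        assert row["mean"] > 0
        assert row["credible"]

    def test_mismatched_parameter_sets_rejected(self, small_fit):
        fit, counts, _ = small_fit
        trials, meta, _ = generate_mpt_dataset("older_gist", n_participants=15, seed=51)
        other = HierarchicalMPT(
            variant="original", n_chains=2, n_warmup=50, n_draws=50, random_state=3
        ).fit(aggregate_trials(trials), meta)
        with pytest.raises(ValueError, match="mismatched"):
            condition_difference(fit, other)
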