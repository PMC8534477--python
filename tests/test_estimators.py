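import warnings

import numpy as np
import pytest

from camap.constraints import ConstraintSet, RangeConstraint, check_satisfaction
from camap.estimators import (
    EstimatorConfig,
    camap_fit,
    cme_estimate,
    cml_estimate,
    map_estimate,
    map_uniform,
    me_estimate,
    ml_estimate,
)
from camap.network import (
    CountTable,
    Network,
    ParameterSet,
    count_sufficient_stats,
    forward_sample,
)
from camap.prior import PriorSpec


@pytest.fixture
def one_binary() -> Network:
    return Network(["A"], {"A": []}, {"A": 2})


def single_counts(*row) -> CountTable:
    return CountTable({"A": np.array([row])})


def uniform_prior(net: Network) -> PriorSpec:
    return PriorSpec.uniform(net)


class TestML:
    def test_one_in_seven(self):
        est = ml_estimate(single_counts(1, 6))
        assert est["A"][0, 0] == pytest.approx(1 / 7)

    def test_zero_row_uniform(self):
        est = ml_estimate(single_counts(0, 0))
        assert np.allclose(est["A"], 0.5)

    def test_nine_one(self):
        est = ml_estimate(single_counts(9, 1))
        assert np.allclose(est["A"], [0.9, 0.1])

    def test_floor_removes_zeros(self):
        est = ml_estimate(single_counts(5, 0), floor=1e-12)
        assert est["A"][0, 1] > 0
        assert est["A"][0].sum() == pytest.approx(1.0)


class TestMAP:
    def test_small_ess_blend(self, one_binary):
        # (1 + 5*0.80) / (7 + 5) = 0.42
        prior = PriorSpec(ParameterSet({"A": np.array([[0.80, 0.20]])}), 0, 0.0)
        est = map_estimate(single_counts(1, 6), prior, 5.0)
        assert round(est["A"][0, 0], 2) == 0.42

    def test_strong_prior_dominates_empty_config(self, one_binary):
        # (0 + 50*0.99) / (3 + 50) = 0.93
        prior = PriorSpec(ParameterSet({"A": np.array([[0.99, 0.01]])}), 0, 0.0)
        est = map_estimate(single_counts(0, 3), prior, 50.0)
        assert round(est["A"][0, 0], 2) == 0.93

    def test_vanishing_ess_approaches_ml(self, one_binary):
        prior = PriorSpec(ParameterSet({"A": np.array([[0.9, 0.1]])}), 0, 0.0)
        est = map_estimate(single_counts(3, 7), prior, 1e-9)
        ml = ml_estimate(single_counts(3, 7))
        assert np.allclose(est["A"], ml["A"], atol=1e-9)

    def test_no_data_returns_prior(self, one_binary):
        prior = PriorSpec(ParameterSet({"A": np.array([[0.7, 0.3]])}), 0, 0.0)
        est = map_estimate(single_counts(0, 0), prior, 10.0)
        assert np.allclose(est["A"], prior["A"])

    def test_blend_interpolates_between_ml_and_prior(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = rng.integers(1, 30, size=3)
            p = rng.dirichlet([1, 1, 1])
            alpha = rng.uniform(0.1, 60)
            prior = PriorSpec(ParameterSet({"A": p[None, :]}), 0, 0.0)
            est = map_estimate(CountTable({"A": n[None, :]}), prior, alpha)
            ml = n / n.sum()
            lo = np.minimum(ml, p) - 1e-12
            hi = np.maximum(ml, p) + 1e-12
            assert np.all((est["A"][0] >= lo) & (est["A"][0] <= hi))

    def test_monotone_in_ess_toward_prior(self):
        prior = PriorSpec(ParameterSet({"A": np.array([[0.9, 0.1]])}), 0, 0.0)
        counts = single_counts(1, 9)
        vals = [
            map_estimate(counts, prior, a)["A"][0, 0]
            for a in (0.5, 1, 2, 5, 10, 50, 500)
        ]
        assert all(a < b for a, b in zip(vals, vals[1:]))
        assert vals[-1] < 0.9


class TestMAPUniform:
    def test_empty_counts_give_uniform(self):
        est = map_uniform(single_counts(0, 0))
        assert np.allclose(est["A"], 0.5)

    def test_three_zero(self):
        est = map_uniform(single_counts(3, 0))
        assert np.allclose(est["A"], [3.5 / 4, 0.5 / 4])

    def test_equals_map_with_explicit_flat_prior(self, one_binary):
        counts = single_counts(4, 2)
        a = map_uniform(counts, ess=1.0)
        b = map_estimate(counts, uniform_prior(one_binary), 1.0)
        assert np.allclose(a["A"], b["A"])


class TestCML:
    def test_empty_constraints_equal_ml(self, two_node_net):
        data = forward_sample(two_node_net, 100, seed=1)
        counts = count_sufficient_stats(data, two_node_net)
        est = cml_estimate(counts, ConstraintSet(), two_node_net)
        ml = ml_estimate(counts)
        for v in two_node_net.nodes:
            assert np.allclose(est[v], ml[v], atol=1e-9)

    def test_active_range_constraint(self, one_binary):
        # ML would put 1/8 on state 0; the lower bound 0.6 binds
        cs = ConstraintSet.from_list([RangeConstraint("A", 0, 0, 0.6, 1.0)])
        est = cml_estimate(single_counts(1, 7), cs, one_binary)
        assert est["A"][0, 0] == pytest.approx(0.6, abs=1e-6)

    def test_beats_random_feasible_probes(self, one_binary):
        cs = ConstraintSet.from_list([RangeConstraint("A", 0, 0, 0.3, 0.9)])
        counts = single_counts(2, 8)
        est = cml_estimate(counts, cs, one_binary)
        n = counts.counts["A"][0].astype(float)

        def ll(theta):
            return float(np.sum(n * np.log(theta)))

        best = ll(est["A"][0])
        rng = np.random.default_rng(2)
        probes = rng.uniform(0.3, 0.9, size=1000)
        for p0 in probes:
            assert best >= ll(np.array([p0, 1 - p0])) - 1e-7


class TestCME:
    def test_loose_slack_gives_uniform(self, one_binary):
        est = me_estimate(single_counts(9, 1), one_binary, me_epsilon=100.0)
        assert np.allclose(est["A"], 0.5, atol=1e-5)

    def test_tight_slack_recovers_ml(self, one_binary):
        est = me_estimate(single_counts(9, 1), one_binary, me_epsilon=1e-8)
        assert np.allclose(est["A"], [0.9, 0.1], atol=1e-3)

    def test_beats_random_probes_on_entropy(self, one_binary):
        cs = ConstraintSet.from_list([RangeConstraint("A", 0, 0, 0.6, 1.0)])
        counts = single_counts(9, 1)
        eps = 0.02
        est = cme_estimate(counts, cs, one_binary, me_epsilon=eps)
        n = counts.counts["A"][0].astype(float)
        ref = cml_estimate(counts, cs, one_binary)["A"][0]

        def ll(theta):
            return float(np.sum(n * np.log(theta)))

        def ent(theta):
            return float(-np.sum(theta * np.log(theta)))

        budget = ll(ref) - eps * 10
        rng = np.random.default_rng(3)
        assert ll(est["A"][0]) >= budget - 1e-6
        for p0 in rng.uniform(0.6, 1.0 - 1e-6, size=1000):
            theta = np.array([p0, 1 - p0])
            if ll(theta) >= budget:
                assert ent(est["A"][0]) >= ent(theta) - 1e-6

    def test_satisfies_constraints(self, brain_net, bt_dataset, bt_constraints):
        counts = count_sufficient_stats(bt_dataset, brain_net)
        est = cme_estimate(counts, bt_constraints, brain_net)
        assert check_satisfaction(est, bt_constraints, tol=1e-6) == []


class TestCamapFit:
    def test_worked_example_with_pinned_prior_and_ess(
        self, bt_counts, bt_prior
    ):
        """With the printed prior shape and the printed local ESS values the
        blend reproduces all eight final estimates at two decimals."""
        ess = {"C": np.array([50.0, 6.0, 50.0, 50.0]), "BT": 1.0, "IS": 1.0}
        est = map_estimate(bt_counts, bt_prior, ess)
        expected = np.array(
            [[0.93, 0.07], [0.62, 0.38], [0.58, 0.42], [0.19, 0.81]]
        )
        assert np.array_equal(np.round(est["C"], 2), expected)

    def test_pipeline_satisfies_constraints(
        self, brain_net, bt_dataset, bt_constraints
    ):
        fit = camap_fit(
            brain_net, bt_dataset, bt_constraints,
            EstimatorConfig(seed=4, n_prior_samples=50),
        )
        assert fit.violations == []
        assert fit.prior is not None and fit.ess is not None
        for v in brain_net.nodes:
            assert np.allclose(fit.params[v].sum(axis=1), 1.0)

    def test_empty_constraints_degenerate_to_map_like(self, two_node_net):
        """No constraints: the pipeline reduces to MAP with a sampled
        near-flat prior and a cross-validated global ESS."""
        data = forward_sample(two_node_net, 50, seed=5)
        fit = camap_fit(
            two_node_net, data, ConstraintSet(),
            EstimatorConfig(seed=6, n_prior_samples=200),
        )
        for v in two_node_net.nodes:
            assert np.allclose(
                fit.prior[v], 1.0 / two_node_net.cardinality(v), atol=0.06
            )
            assert np.all(fit.ess.alpha(v) == fit.ess.global_ess[v])

    def test_infeasible_constraints_abort(self, one_binary):
        import pandas as pd

        from camap.network import Dataset

        cs = ConstraintSet.from_list([
            RangeConstraint("A", 0, 0, 0.7, 1.0),
            RangeConstraint("A", 0, 0, 0.0, 0.3),
        ])
        data = Dataset(pd.DataFrame({"A": [0, 1, 0]}))
        with pytest.raises(ValueError, match="infeasible"):
            camap_fit(one_binary, data, cs, EstimatorConfig(seed=7))

    def test_deterministic_given_seed(
        self, brain_net, bt_dataset, bt_constraints
    ):
        cfg = EstimatorConfig(seed=8, n_prior_samples=30)
        a = camap_fit(brain_net, bt_dataset, bt_constraints, cfg)
        b = camap_fit(brain_net, bt_dataset, bt_constraints, cfg)
        for v in brain_net.nodes:
            assert np.array_equal(a.params[v], b.params[v])

    def test_random_instances_satisfy_finite_bound_constraints(self):
        """End-to-end: generated constraints (always truth-consistent) are
        satisfied by the final estimates."""
        from camap.experiments import generate_constraints_from_truth, make_test_network

        rng = np.random.default_rng(9)
        for _ in range(10):
            net = make_test_network("skewed", 4, 2, seed=rng)
            data = forward_sample(net, 25, seed=int(rng.integers(2**31)))
            cs = generate_constraints_from_truth(net.true_params, net, seed=rng)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = camap_fit(
                    net, data, cs,
                    EstimatorConfig(seed=int(rng.integers(2**31)),
                                    n_prior_samples=50),
                )
            unresolved = [
                v for v in fit.violations if v.margin > 1e-6
            ]
            assert unresolved == []
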