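import itertools
import math

import numpy as np
import pytest
from scipy import stats

from elicitbn import (HybridNetwork, NodeSpec, build_network,
                      compare_prior_regimes, condition, forward_sample,
                      load_paper_replica, network_from_config,
                      network_to_config, to_dot)
from elicitbn.errors import (ConfigurationError, ComparisonError, CycleError,
                             DegenerateEvidenceError, SchemaError,
                             ValidationError)
from elicitbn.priors import BetaPrior, PriorSpec, StudentTPrior


def cat_root(node_id, alpha, beta, categories=("yes", "no")):
    return NodeSpec(node_id, "categorical", categories=categories,
                    prior=PriorSpec(node_id, "beta", BetaPrior(alpha, beta)))


def cat_child(node_id, parents, table, categories=("yes", "no")):
    return NodeSpec(node_id, "categorical", categories=categories,
                    parents=parents, model_class="cpt",
                    model_params={"table": table})


def bernoulli_net(p_a=0.6, p_b_given=(0.9, 0.2)):
    """A -> B, both binary, exactly enumerable."""
    a = cat_root("A", p_a * 10, (1 - p_a) * 10)
    b = cat_child("B", ("A",), {("yes",): [p_b_given[0], 1 - p_b_given[0]],
                                ("no",): [p_b_given[1], 1 - p_b_given[1]]})
    return build_network([a, b], categorical_mode="fixed_proportion")


class TestBuildNetwork:
    def test_twelve_root_nodes_build_an_edgeless_network(self):
        specs = [cat_root(f"n{i}", 2.0, 2.0) for i in range(12)]
        bn = build_network(specs)
        assert len(bn.nodes) == 12 and bn.edges == ()

    def test_chain_structure_derived_from_parent_lists(self):
        a = cat_root("A", 2.0, 2.0)
        b = cat_child("B", ("A",), {"*": [0.5, 0.5]})
        c = cat_child("C", ("B",), {"*": [0.5, 0.5]})
        bn = build_network([a, b, c])
        assert set(bn.edges) == {("A", "B"), ("B", "C")}
        assert bn.order.index("A") < bn.order.index("B") < bn.order.index("C")

    def test_cycle_is_rejected_with_the_offending_path(self):
        a = cat_child("A", ("B",), {"*": [0.5, 0.5]})
        b = cat_child("B", ("A",), {"*": [0.5, 0.5]})
        with pytest.raises(CycleError, match="A|B"):
            build_network([a, b])

    def test_dangling_parent_is_a_reference_error(self):
        b = cat_child("B", ("ghost",), {"*": [0.5, 0.5]})
        with pytest.raises(SchemaError, match="ghost"):
            build_network([b])

    def test_root_without_prior_rejected(self):
        with pytest.raises(ConfigurationError):
            NodeSpec("A", "categorical", categories=("yes", "no"))


class TestForwardSample:
    def test_fixed_proportion_category_frequency(self):
        bn = build_network([cat_root("A", 5.0, 5.0)],
                           categorical_mode="fixed_proportion")
        frame = forward_sample(bn, 100_000, seed=3)
        assert (frame["A"] == "yes").mean() == pytest.approx(0.5, abs=0.005)

    def test_prior_predictive_frequency_matches_the_beta_mean(self):
        # male-proportion prior Beta(7.62, 5.76): mean 0.5695
        bn = build_network([cat_root("gender", 7.62, 5.76,
                                     categories=("male", "female"))])
        frame = forward_sample(bn, 100_000, seed=4)
        assert (frame["gender"] == "male").mean() == pytest.approx(
            7.62 / (7.62 + 5.76), abs=0.005)

    def test_continuous_root_matches_its_t_prior_distribution(self):
        spec = NodeSpec("x", "continuous",
                        prior=PriorSpec("x", "student_t",
                                        StudentTPrior(10.0, 2.0, 7)))
        bn = build_network([spec])
        draws = forward_sample(bn, 10_000, seed=5)["x"].to_numpy()
        ks = stats.kstest(draws, lambda x: stats.t.cdf(x, 7, loc=10.0, scale=2.0))
        # 1% critical value for the KS statistic at n = 10^4
        assert ks.statistic < 1.63 / math.sqrt(len(draws))

    def test_truncated_prior_respects_support(self):
        spec = NodeSpec("marker", "continuous", support=(0.0, math.inf),
                        prior=PriorSpec("marker", "student_t",
                                        StudentTPrior(130.29, 207.84, 7)))
        bn = build_network([spec])
        draws = forward_sample(bn, 5_000, seed=6)["marker"].to_numpy()
        assert draws.min() >= 0.0

    def test_reproducible_given_seed(self):
        bn = bernoulli_net()
        f1 = forward_sample(bn, 500, seed=11)
        f2 = forward_sample(bn, 500, seed=11)
        assert f1.equals(f2)

    def test_linear_child_follows_its_gaussian_model(self):
        root = NodeSpec("x", "continuous",
                        prior=PriorSpec("x", "student_t",
                                        StudentTPrior(0.0, 1.0, 30)))
        child = NodeSpec("y", "continuous", parents=("x",), model_class="linear",
                         model_params={"intercept": 1.0,
                                       "coefficients": {"x": 2.0}, "sd": 0.1})
        frame = forward_sample(build_network([root, child]), 50_000, seed=8)
        resid = frame["y"] - (1.0 + 2.0 * frame["x"])
        assert resid.mean() == pytest.approx(0.0, abs=0.005)
        assert resid.std() == pytest.approx(0.1, abs=0.005)


def enumerate_posterior(p_roots, cpts, evidence):
    """Exact inference on a small all-binary network by full enumeration.

    ``p_roots``: {node: P(node=1)}; ``cpts``: {node: (parents, {combo: P(node=1)})}.
    Returns {node: P(node=1 | evidence)}.
    """
    nodes = list(p_roots) + list(cpts)
    joint = {}
    for combo in itertools.product([0, 1], repeat=len(nodes)):
        state = dict(zip(nodes, combo))
        p = 1.0
        for n, pr in p_roots.items():
            p *= pr if state[n] == 1 else 1.0 - pr
        for n, (parents, table) in cpts.items():
            p1 = table[tuple(state[q] for q in parents)]
            p *= p1 if state[n] == 1 else 1.0 - p1
        joint[combo] = p
    keep = {c: p for c, p in joint.items()
            if all(c[nodes.index(n)] == v for n, v in evidence.items())}
    z = sum(keep.values())
    return {n: sum(p for c, p in keep.items() if c[nodes.index(n)] == 1) / z
            for n in nodes}


class TestCondition:
    def test_two_node_posterior_matches_enumeration(self):
        bn = bernoulli_net()
        post = condition(bn, {"B": "yes"}, 100_000, seed=9)
        exact = 0.6 * 0.9 / (0.6 * 0.9 + 0.4 * 0.2)
        p_hat = post.category_probs("A")["yes"]
        se = math.sqrt(exact * (1 - exact) / post.ess)
        assert abs(p_hat - exact) < 3.0 * se

    def test_four_node_binary_network_matches_enumeration(self):
        """Likelihood weighting against the brute-force joint on a diamond."""
        a = cat_root("A", 6.0, 4.0)
        b = cat_child("B", ("A",), {("yes",): [0.7, 0.3], ("no",): [0.2, 0.8]})
        c = cat_child("C", ("A",), {("yes",): [0.9, 0.1], ("no",): [0.4, 0.6]})
        d = cat_child("D", ("B", "C"), {("yes", "yes"): [0.95, 0.05],
                                        ("yes", "no"): [0.5, 0.5],
                                        ("no", "yes"): [0.6, 0.4],
                                        ("no", "no"): [0.1, 0.9]})
        bn = build_network([a, b, c, d], categorical_mode="fixed_proportion")
        post = condition(bn, {"D": "yes"}, 100_000, seed=10)
        # category index 1 ('yes') maps to state 1 in the enumeration
        exact = enumerate_posterior(
            {"A": 0.6},
            {"B": (("A",), {(1,): 0.7, (0,): 0.2}),
             "C": (("A",), {(1,): 0.9, (0,): 0.4}),
             "D": (("B", "C"), {(1, 1): 0.95, (1, 0): 0.5,
                                (0, 1): 0.6, (0, 0): 0.1})},
            {"D": 1})
        for node in ("A", "B", "C"):
            p_hat = post.category_probs(node).get("yes", 0.0)
            se = math.sqrt(max(exact[node] * (1 - exact[node]), 1e-6) / post.ess)
            assert abs(p_hat - exact[node]) < 3.0 * se, node

    def test_empty_evidence_reproduces_forward_sampling(self):
        bn = bernoulli_net()
        post = condition(bn, {}, 20_000, seed=12)
        assert np.all(post.weights == 1.0)
        frame = forward_sample(bn, 20_000, seed=12)
        assert post.samples.equals(frame)

    def test_evidence_on_a_root_is_a_point_mass(self):
        bn = bernoulli_net()
        post = condition(bn, {"A": "no"}, 5_000, seed=13)
        assert post.category_probs("A") == {"no": 1.0}

    def test_unknown_category_rejected_before_sampling(self):
        bn = bernoulli_net()
        with pytest.raises(ValidationError, match="unknown"):
            condition(bn, {"A": "unknown"}, 100, seed=1)

    def test_impossible_category_gives_degenerate_evidence(self):
        a = cat_root("A", 5.0, 5.0)
        b = cat_child("B", ("A",), {"*": [1.0, 0.0]})
        bn = build_network([a, b], categorical_mode="fixed_proportion")
        with pytest.raises(DegenerateEvidenceError):
            condition(bn, {"B": "no"}, 1_000, seed=1)

    def test_evidence_outside_support_rejected(self):
        spec = NodeSpec("marker", "continuous", support=(0.0, math.inf),
                        prior=PriorSpec("marker", "student_t",
                                        StudentTPrior(100.0, 50.0, 7)))
        bn = build_network([spec])
        with pytest.raises(ValidationError, match="support"):
            condition(bn, {"marker": -5.0}, 100, seed=1)


class TestComparePriorRegimes:
    def flat_version(self, informative):
        flat = [cat_root("A", 1.0, 1.0),
                cat_child("B", ("A",), {("yes",): [0.9, 0.1],
                                        ("no",): [0.2, 0.8]})]
        return build_network(flat, categorical_mode="fixed_proportion")

    def test_identical_regimes_have_zero_divergence(self):
        bn = bernoulli_net()
        report = compare_prior_regimes(bn, bn, {}, 20_000, seed=14)
        assert (report["tv_distance"].abs() < 0.02).all()

    def test_informative_and_flat_priors_disagree_without_evidence(self):
        bn = bernoulli_net()
        report = compare_prior_regimes(bn, self.flat_version(bn), {},
                                       50_000, seed=15)
        row = report[report["node_id"] == "A"].iloc[0]
        # prior means 0.6 vs 0.5: the TV distance estimate reflects it
        assert row["tv_distance"] == pytest.approx(0.1, abs=0.02)

    def test_evidence_shrinks_the_disagreement(self):
        bn = bernoulli_net()
        flat = self.flat_version(bn)
        free = compare_prior_regimes(bn, flat, {}, 50_000, seed=16)
        clamped = compare_prior_regimes(bn, flat, {"A": "yes"}, 50_000, seed=16)
        tv_free = free.set_index("node_id")["tv_distance"]
        tv_clamped = clamped.set_index("node_id")["tv_distance"]
        assert tv_clamped["A"] < tv_free["A"]
        assert tv_clamped["B"] <= tv_free["B"] + 0.01

    def test_structure_mismatch_rejected(self):
        bn = bernoulli_net()
        other = build_network([cat_root("A", 2.0, 2.0)])
        with pytest.raises(ComparisonError):
            compare_prior_regimes(bn, other, {}, 100, seed=1)


class TestDotExport:
    def test_edgeless_network(self):
        bn = build_network([cat_root("A", 2, 2), cat_root("B", 2, 2)])
        dot = to_dot(bn)
        assert dot.count("[shape=") == 2 and "->" not in dot

    def test_edge_rendering(self):
        bn = bernoulli_net()
        assert '"A" -> "B";' in to_dot(bn)

    def test_deterministic_output(self):
        bn = bernoulli_net()
        assert to_dot(bn) == to_dot(bn)


class TestPaperReplica:
    VARIABLES = {"ca19_9", "age", "tumor_size", "gender", "bmi",
                 "year_of_diagnosis", "tumor_location", "diabetes", "symptoms",
                 "asa_score", "resectability", "neoadjuvant"}

    def test_contains_the_twelve_diagnosis_variables(self):
        bn = load_paper_replica()
        assert set(bn.nodes) == self.VARIABLES

    def test_forward_sampling_yields_a_twelve_column_table(self):
        frame = forward_sample(load_paper_replica(), 1000, seed=17)
        assert frame.shape == (1000, 12)

    def test_dot_export_has_one_statement_per_node(self):
        dot = to_dot(load_paper_replica())
        assert dot.count("[shape=") == 12

    def test_config_round_trip(self):
        bn = load_paper_replica()
        back = network_from_config(network_to_config(bn))
        assert set(back.nodes) == set(bn.nodes)
        assert set(back.edges) == set(bn.edges)
        f1 = forward_sample(bn, 200, seed=18)
        f2 = forward_sample(back, 200, seed=18)
        assert f1.equals(f2)
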