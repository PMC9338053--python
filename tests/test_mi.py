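import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tfnet import (
    bootstrap_consensus,
    dpi_prune,
    infer_network,
    mutual_information,
    permutation_significance,
    simulate_expression,
)
from tfnet.datatypes import GroundTruthModel, MIParams, SignedNetwork

from conftest import make_expression
from oracles import dpi_bruteforce, mi_bruteforce


class TestMutualInformation:
    def test_monotone_function_saturates_at_log_bins(self, rng):
        n_bins = 4
        x = rng.normal(size=n_bins**2)
        y = 3.0 * x + 1.0  # strictly increasing in x
        assert mutual_information(x, y, n_bins) == pytest.approx(
            np.log(n_bins), abs=1e-12
        )

    def test_self_information_is_log_bins(self, rng):
        x = rng.normal(size=25)
        assert mutual_information(x, x, 5) == pytest.approx(np.log(5), abs=1e-12)

    def test_constant_vector_warns_and_returns_zero(self, rng):
        x = np.ones(20)
        y = rng.normal(size=20)
        with pytest.warns(UserWarning, match="constant"):
            assert mutual_information(x, y, 4) == 0.0

    def test_independent_permutation_below_null_quantile(self, rng):
        x = rng.normal(size=400)
        y = rng.permutation(x)
        obs = mutual_information(x, y)
        null = np.array(
            [mutual_information(rng.permutation(x), y) for _ in range(99)]
        )
        assert obs < np.quantile(null, 0.95) + 1e-9

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match=">= 8"):
            mutual_information([1, 2, 3], [1, 2, 3])

    def test_missing_values_removed_pairwise(self, rng):
        x = rng.normal(size=30)
        y = 2 * x
        x_m, y_m = x.copy(), y.copy()
        x_m[:5] = np.nan
        assert mutual_information(x_m, y_m, 5) == pytest.approx(
            mutual_information(x[5:], y[5:], 5)
        )

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        data=st.lists(
            st.tuples(
                st.floats(-50, 50, allow_nan=False),
                st.floats(-50, 50, allow_nan=False),
            ),
            min_size=8,
            max_size=64,
        ),
        n_bins=st.integers(2, 6),
    )
    def test_symmetric_and_nonnegative(self, data, n_bins):
        x = np.array([a for a, _ in data])
        y = np.array([b for _, b in data])
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m_xy = mutual_information(x, y, n_bins)
            m_yx = mutual_information(y, x, n_bins)
        assert m_xy == m_yx  # bitwise symmetry
        assert m_xy >= 0.0

    def test_matches_bruteforce_contingency(self, rng):
        for _ in range(200):
            n = int(rng.integers(8, 60))
            b = int(rng.integers(2, 7))
            x = rng.normal(size=n)
            y = rng.normal(size=n) + rng.uniform(-1, 1) * x
            assert mutual_information(x, y, b) == pytest.approx(
                mi_bruteforce(x, y, b), abs=1e-12
            )


class TestPermutationSignificance:
    def _expr_with_child(self, rng, noise=0.0):
        n = 40
        tf = np.repeat([0.0, 2.0], n // 2) + rng.normal(0, 0.25, n)
        child = tf + rng.normal(0, noise, n) if noise else tf.copy()
        others = rng.normal(0, 1, (4, n))
        return make_expression(np.vstack([tf, child, others]),
                               genes=["tf", "child", "a", "b", "c", "d"])

    def test_minimum_attainable_pvalue(self, rng):
        expr = self._expr_with_child(rng)
        out = permutation_significance(expr, "tf", MIParams(), seed=0)
        assert out["pvalue"].min() == pytest.approx(1 / 101)

    def test_deterministic_child_retained_at_floor_p(self, rng):
        expr = self._expr_with_child(rng)
        row = permutation_significance(expr, "tf", MIParams(), seed=0).set_index("target").loc["child"]
        assert row["pvalue"] == pytest.approx(1 / 101)
        assert bool(row["retained"])

    def test_null_retention_at_or_below_nominal(self):
        # independent TF: BH at alpha=0.05 over 200 targets should retain
        # ~alpha*200 targets or fewer on average
        counts = []
        for seed in range(3):
            r = np.random.default_rng(1000 + seed)
            expr = make_expression(r.normal(0, 1, (201, 60)))
            out = permutation_significance(expr, "g0", MIParams(), seed=seed)
            counts.append(int(out["retained"].sum()))
        assert np.mean(counts) <= 200 * 0.05

    def test_unknown_tf_rejected(self, rng):
        expr = make_expression(rng.normal(size=(3, 20)))
        with pytest.raises(KeyError):
            permutation_significance(expr, "nope", MIParams(), seed=0)


def _random_signed_network(rng, n_nodes, p_edge):
    nodes = [chr(65 + i) for i in range(n_nodes)]
    net = SignedNetwork(nodes=nodes, edges={})
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p_edge:
                net.add_edge(nodes[i], nodes[j], mi=float(rng.uniform(0.01, 1)), sign=1, consensus=1.0)
    return net


class TestDPI:
    def test_weakest_triangle_edge_removed(self):
        net = SignedNetwork(nodes=["A", "B", "C"], edges={})
        net.add_edge("A", "B", 0.9, 1, 1.0)
        net.add_edge("B", "C", 0.8, 1, 1.0)
        net.add_edge("A", "C", 0.3, 1, 1.0)
        pruned = dpi_prune(net, 0.0)
        assert set(pruned.edges) == {("A", "B"), ("B", "C")}

    def test_exact_tie_removes_nothing(self):
        net = SignedNetwork(nodes=["A", "B", "C"], edges={})
        for a, b in [("A", "B"), ("B", "C"), ("A", "C")]:
            net.add_edge(a, b, 0.5, 1, 1.0)
        assert set(dpi_prune(net, 0.0).edges) == set(net.edges)

    @pytest.mark.parametrize("tolerance", [0.0, 0.1])
    def test_matches_bruteforce_on_random_graphs(self, tolerance):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            n = int(rng.integers(3, 9))
            net = _random_signed_network(rng, n, 0.6)
            expected = dpi_bruteforce(
                {k: e.mi for k, e in net.edges.items()}, tolerance
            )
            assert set(dpi_prune(net, tolerance).edges) == set(expected)

    def test_no_surviving_triangle_violates_dpi(self):
        # every output triangle was an input triangle, so the frozen-set
        # decision pass guarantees no remaining triangle has its weakest
        # edge strictly below the minimum of the other two
        import itertools

        for g_seed in range(20):
            net = _random_signed_network(np.random.default_rng(g_seed), 8, 0.7)
            pruned = dpi_prune(net, 0.0)
            mis = {k: e.mi for k, e in pruned.edges.items()}
            def key(a, b):
                return (a, b) if a <= b else (b, a)
            for a, b, c in itertools.combinations(pruned.nodes, 3):
                trio = [key(a, b), key(a, c), key(b, c)]
                if all(t in mis for t in trio):
                    vals = sorted(mis[t] for t in trio)
                    assert not vals[0] < vals[1]  # weakest not strictly below


class TestBootstrapAndInference:
    def _chain_model(self, noise=0.05):
        return GroundTruthModel(
            tf_levels={"A": 3, "B": 2, "C": 1},
            edges={("A", "B"): 0.8, ("B", "C"): 0.8},
            targets=[],
            condition_effects={
                ("ctl", 1): np.zeros(1),
                ("inj", 1): np.array([2.0]),
                ("ctl", 3): np.zeros(1),
                ("inj", 3): np.array([-1.5]),
            },
            noise_sd=noise,
            seed=0,
        )

    FAST = MIParams(n_permutations=30, n_bootstraps=25, consensus=0.95)

    def test_deterministic_pair_kept_with_full_consensus(self):
        model = self._chain_model(noise=0.0)
        expr = simulate_expression(model, 10, seed=2)
        net = bootstrap_consensus(expr, ["A", "B", "C"], self.FAST, seed=0)
        assert net.has_edge("A", "B")
        edge = net.edges[("A", "B")]
        assert edge.consensus == 1.0
        assert edge.sign == +1

    def test_negative_weight_pair_signed_negative(self):
        model = self._chain_model(noise=0.0)
        model.edges[("A", "B")] = -0.8
        expr = simulate_expression(model, 10, seed=2)
        net = bootstrap_consensus(expr, ["A", "B", "C"], self.FAST, seed=0)
        assert net.edges[("A", "B")].sign == -1

    def test_independent_pair_absent(self, rng):
        expr = make_expression(rng.normal(size=(4, 40)))
        net = bootstrap_consensus(expr, ["g0", "g1"], self.FAST, seed=0)
        assert not net.has_edge("g0", "g1")

    def test_small_sample_count_rejected(self, rng):
        expr = make_expression(rng.normal(size=(3, 10)))
        with pytest.raises(ValueError, match="bootstrap"):
            bootstrap_consensus(expr, ["g0", "g1"], self.FAST, seed=0)

    def test_chain_inference_prunes_indirect_edge(self):
        # small observation noise separates the direct and indirect MIs;
        # at exactly zero noise all three MIs tie and the strict DPI rule
        # keeps the triangle intact by contract
        model = self._chain_model(noise=0.05)
        expr = simulate_expression(model, 25, seed=3)
        net = infer_network(expr, ["A", "B", "C"], self.FAST, seed=1)
        assert net.has_edge("A", "B")
        assert net.has_edge("B", "C")
        assert not net.has_edge("A", "C")

    def test_empty_tf_list_rejected(self, rng):
        expr = make_expression(rng.normal(size=(3, 20)))
        with pytest.raises(ValueError, match="tf_list"):
            infer_network(expr, [], MIParams(), seed=0)

    def test_rerun_same_seed_identical(self):
        model = self._chain_model()
        expr = simulate_expression(model, 10, seed=2)
        n1 = infer_network(expr, ["A", "B", "C"], self.FAST, seed=5)
        n2 = infer_network(expr, ["A", "B", "C"], self.FAST, seed=5)
        assert n1.edges == n2.edges
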