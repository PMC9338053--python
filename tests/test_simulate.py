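import numpy as np
import pytest
from scipy import stats

from tfnet import (
    simulate_de_table,
    simulate_evidence,
    simulate_expression,
    simulate_module_expression,
    simulate_network,
)
from tfnet.datatypes import GroundTruthModel

from conftest import make_expression


class TestSimulateNetwork:
    def test_minimal_pyramid_is_a_chain(self):
        model = simulate_network(1, 1, 1, 10, 1.0, 0.0, 0, seed=7)
        assert model.tf_tf_edges() == {("TOP1", "MID1"), ("MID1", "BOT1")}
        assert len(model.targets) == 10
        assert all(w > 0 for w in model.edges.values())

    def test_fully_repressive(self):
        model = simulate_network(2, 2, 2, 5, 0.5, 1.0, 0, seed=3)
        assert all(w < 0 for w in model.edges.values())

    def test_determinism(self):
        a = simulate_network(2, 3, 4, 50, 0.3, 0.3, 1, seed=11)
        b = simulate_network(2, 3, 4, 50, 0.3, 0.3, 1, seed=11)
        assert a.edges == b.edges
        assert a.tf_levels == b.tf_levels
        assert a.cycle_members == b.cycle_members

    def test_spanning_guarantees(self):
        model = simulate_network(3, 4, 5, 20, 0.1, 0.2, 0, seed=5)
        edges = model.tf_tf_edges()
        tops = [t for t, l in model.tf_levels.items() if l == 3]
        mids = [t for t, l in model.tf_levels.items() if l == 2]
        bots = [t for t, l in model.tf_levels.items() if l == 1]
        assert all(any((t, m) in edges for m in mids) for t in tops)
        assert all(any((t, m) in edges for t in tops) for m in mids)
        assert all(any((m, b) in edges for m in mids) for b in bots)
        # each target has exactly one regulator
        for g in model.targets:
            regs = [r for (r, t) in model.edges if t == g]
            assert len(regs) == 1

    def test_cycle_groups_validated(self):
        model = simulate_network(2, 3, 4, 10, 0.3, 0.2, 1, seed=2)
        (members,) = model.cycle_members.values()
        u, v = members
        assert model.tf_levels[u] == model.tf_levels[v]
        assert (u, v) in model.edges and (v, u) in model.edges
        with pytest.raises(ValueError, match="cycle group"):
            simulate_network(1, 1, 1, 5, 0.5, 0.0, 3, seed=1)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            simulate_network(0, 1, 1, 5, 0.5, 0.0, 0, seed=1)
        with pytest.raises(ValueError):
            simulate_network(1, 1, 1, 5, 0.0, 0.0, 0, seed=1)


def _two_gene_model(weight: float, effect: float = 2.0, noise_sd: float = 0.0):
    return GroundTruthModel(
        tf_levels={"A": 2, "B": 1},
        edges={("A", "B"): weight},
        targets=[],
        condition_effects={
            ("control", 1): np.zeros(1),
            ("injury", 1): np.array([effect]),
        },
        noise_sd=noise_sd,
        seed=0,
    )


class TestSimulateExpression:
    def test_zero_noise_child_is_exact_multiple(self):
        model = _two_gene_model(weight=0.7)
        expr = simulate_expression(model, 5, seed=1)
        a, b = expr.gene_values("A"), expr.gene_values("B")
        assert np.max(np.abs(b - 0.7 * a)) < 1e-12
        assert np.corrcoef(a, b)[0, 1] == pytest.approx(1.0)

    def test_zero_noise_negative_weight_anticorrelates(self):
        model = _two_gene_model(weight=-0.5)
        expr = simulate_expression(model, 5, seed=1)
        r = np.corrcoef(expr.gene_values("A"), expr.gene_values("B"))[0, 1]
        assert r == pytest.approx(-1.0)

    def test_noisy_unit_weight_child_highly_correlated(self):
        # corr = 1/sqrt(1 + sigma^2/var(parent)); with parent variance ~1
        # (effect 2 on half the samples) and sigma 0.25, corr ~ 0.97 > 0.9
        model = _two_gene_model(weight=1.0, noise_sd=0.25)
        expr = simulate_expression(model, 50, seed=42)
        r = np.corrcoef(expr.gene_values("A"), expr.gene_values("B"))[0, 1]
        assert r > 0.9

    def test_structural_equations_exact_at_zero_noise(self):
        model = simulate_network(
            2, 3, 4, 30, 0.3, 0.3, 0, seed=9, noise_sd=0.0
        )
        expr = simulate_expression(model, 4, seed=5)
        frame = expr.to_frame()
        parents = {}
        for (r, t), w in model.edges.items():
            parents.setdefault(t, []).append((r, w))
        top = max(model.tf_levels.values())
        for gene in expr.gene_ids:
            if gene in model.tf_levels and model.tf_levels[gene] == top:
                continue
            expected = np.zeros(expr.n_samples)
            for r, w in sorted(parents.get(gene, [])):
                expected += w * frame.loc[r].to_numpy()
            assert np.max(np.abs(frame.loc[gene].to_numpy() - expected)) < 1e-12

    def test_determinism_and_metadata_validity(self):
        model = simulate_network(1, 2, 2, 10, 0.5, 0.2, 0, seed=4)
        e1 = simulate_expression(model, 3, seed=8)
        e2 = simulate_expression(model, 3, seed=8)
        assert np.array_equal(e1.values, e2.values)
        assert e1.sample_ids == e2.sample_ids
        assert set(e1.metadata.columns) >= {"condition", "timepoint", "replicate"}

    def test_unknown_condition_rejected(self):
        model = simulate_network(1, 1, 1, 5, 0.5, 0.0, 0, seed=1)
        with pytest.raises(ValueError, match="unknown condition"):
            simulate_expression(model, 3, conditions=("martian",), seed=1)

    def test_cycle_group_members_share_driver(self):
        model = simulate_network(2, 4, 4, 10, 0.3, 0.0, 1, seed=6, noise_sd=0.0)
        expr = simulate_expression(model, 10, seed=3)
        (members,) = model.cycle_members.values()
        u, v = members
        # zero noise: both members = own parental input + the same driver,
        # so subtracting parental input leaves identical residuals
        frame = expr.to_frame()
        parents = {}
        for (r, t), w in model.edges.items():
            parents.setdefault(t, []).append((r, w))
        def residual(g):
            ext = np.zeros(expr.n_samples)
            for r, w in parents.get(g, []):
                if r in members:
                    continue
                ext += w * frame.loc[r].to_numpy()
            return frame.loc[g].to_numpy() - ext
        assert np.max(np.abs(residual(u) - residual(v))) < 1e-12


class TestSimulateEvidence:
    def _many_edge_model(self):
        tops = [f"T{i}" for i in range(10)]
        bots = [f"U{i}" for i in range(10)]
        edges = {(t, u): 1.0 for t in tops for u in bots}
        return GroundTruthModel(
            tf_levels={**{t: 2 for t in tops}, **{u: 1 for u in bots}},
            edges=edges,
            targets=["G1"],
            condition_effects={("c", 1): np.zeros(10)},
            noise_sd=0.1,
            seed=0,
        )

    def test_perfect_evidence_equals_truth(self):
        model = simulate_network(2, 3, 4, 10, 0.4, 0.2, 0, seed=3)
        ev = simulate_evidence(model, tpr=1.0, fpr=0.0, seed=1)
        assert ev.pairs == model.tf_tf_edges()

    def test_zero_tpr_empty(self):
        model = simulate_network(2, 3, 4, 10, 0.4, 0.2, 0, seed=3)
        assert len(simulate_evidence(model, tpr=0.0, fpr=0.0, seed=1)) == 0

    def test_tpr_count_within_binomial_band(self):
        model = self._many_edge_model()  # 100 true TF-TF edges
        ev = simulate_evidence(model, tpr=0.8, fpr=0.0, seed=12)
        assert 69 <= len(ev) <= 90  # central 99% binomial(100, 0.8) band

    def test_fpr_adds_only_false_ordered_pairs(self):
        model = simulate_network(2, 3, 4, 10, 0.4, 0.2, 0, seed=3)
        ev = simulate_evidence(model, tpr=0.0, fpr=1.0, seed=1)
        assert not (ev.pairs & model.tf_tf_edges())
        tfs = set(model.tf_levels)
        assert all(a in tfs and b in tfs and a != b for a, b in ev.pairs)


class TestSimulateDETable:
    def test_identical_groups_give_zero_logfc(self):
        expr = make_expression(
            np.tile([1.0, 2.0, 3.0, 1.0, 2.0, 3.0], (2, 1)),
            conditions=["a"] * 3 + ["b"] * 3,
        )
        de = simulate_de_table(None, expr, ("a", "b"))
        assert de["logFC"].tolist() == [0.0, 0.0]
        assert (de["pvalue"] == 1.0).all()

    def test_condition_effect_recovered_exactly_at_zero_noise(self):
        model = _two_gene_model(weight=1.0, effect=2.0)
        expr = simulate_expression(model, 5, seed=1)
        de = simulate_de_table(model, expr, ("injury", "control"))
        assert de.loc[de["gene"] == "A", "logFC"].iloc[0] == pytest.approx(2.0)

    def test_null_pvalues_uniform(self, rng):
        values = rng.normal(0, 1, (1000, 100))
        expr = make_expression(values, conditions=["a"] * 50 + ["b"] * 50)
        de = simulate_de_table(None, expr, ("a", "b"))
        ks = stats.kstest(de["pvalue"], "uniform")
        assert ks.pvalue > 0.01

    def test_too_few_replicates_rejected(self):
        expr = make_expression(np.ones((2, 3)), conditions=["a", "a", "b"])
        with pytest.raises(ValueError, match="replicates"):
            simulate_de_table(None, expr, ("a", "b"))


class TestModuleGenerator:
    def test_planted_structure_and_determinism(self):
        e1, l1, t1 = simulate_module_expression(seed=2)
        e2, l2, t2 = simulate_module_expression(seed=2)
        assert np.array_equal(e1.values, e2.values)
        assert (l1 == l2).all()
        assert set(l1.unique()) == {0, 1, 2, 3}
        # within-module correlation near the planted level, between near 0
        f = e1.to_frame()
        m1 = l1.index[l1 == 1][:10]
        within = np.corrcoef(f.loc[m1].to_numpy())
        off = within[np.triu_indices_from(within, 1)]
        assert 0.5 < off.mean() < 0.9
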