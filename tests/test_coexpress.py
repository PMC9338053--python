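import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tfnet import (
    detect_modules,
    module_eigengenes,
    module_overlap,
    module_trait_association,
    pick_soft_threshold,
    regress_covariates,
    signed_adjacency,
    simulate_module_expression,
    tom_dissimilarity,
)
from tfnet.coexpress import scale_free_fit

from conftest import make_expression
from oracles import hypergeom_tail_bruteforce, tom_bruteforce


class TestSignedAdjacency:
    def test_perfect_correlation_gives_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        expr = make_expression(np.vstack([x, 2 * x + 1]))
        adj = signed_adjacency(expr, beta=10)
        assert adj.iloc[0, 1] == pytest.approx(1.0)

    def test_perfect_anticorrelation_gives_zero(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        expr = make_expression(np.vstack([x, -x]))
        adj = signed_adjacency(expr, beta=10)
        assert adj.iloc[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_zero_correlation_gives_half_to_the_beta(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])  # exactly orthogonal
        expr = make_expression(np.vstack([x, y]))
        adj = signed_adjacency(expr, beta=10)
        assert adj.iloc[0, 1] == pytest.approx(0.5**10, abs=1e-15)

    def test_constant_gene_warned_and_zeroed(self, rng):
        expr = make_expression(
            np.vstack([np.ones(6), rng.normal(size=6)])
        )
        with pytest.warns(UserWarning, match="constant"):
            adj = signed_adjacency(expr, beta=2)
        assert adj.iloc[0, 1] == pytest.approx(0.25)  # ((1+0)/2)^2


class TestScaleFreeFit:
    def test_power_law_degrees_fit_well(self):
        # inverse-CDF grid of a Pareto(gamma=2.5): p(k) ~ k^-2.5 exactly in
        # the continuum; the binned regression should be near-perfect
        u = (np.arange(5000) + 0.5) / 5000
        k = (1 - u) ** (-1 / 1.5)  # Pareto with alpha = 1.5 -> p(k) ~ k^-2.5
        fit, slope = scale_free_fit(k)
        assert slope < 0
        assert fit > 0.95

    def test_noise_expression_never_reaches_target(self, rng):
        expr = make_expression(rng.normal(size=(60, 20)))
        with pytest.warns(UserWarning, match="no candidate power"):
            beta, table = pick_soft_threshold(expr, betas=tuple(range(1, 8)))
        assert len(table) == 7  # full fit table always emitted
        assert beta == int(table.loc[table["fit"].idxmax(), "beta"])

    def test_fit_table_schema(self, rng):
        expr = make_expression(rng.normal(size=(40, 12)))
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _beta, table = pick_soft_threshold(expr, betas=(1, 2, 3))
        assert list(table.columns) == ["beta", "fit", "slope", "mean_k"]


class TestTOM:
    def test_full_clique_has_zero_dissimilarity(self):
        a = np.ones((3, 3))
        d = tom_dissimilarity(a)
        assert np.allclose(d.to_numpy(), 0.0)

    def test_unconnected_pair_fully_dissimilar(self):
        a = np.eye(4)
        a[0, 1] = a[1, 0] = 0.0
        d = tom_dissimilarity(a)
        assert d.iloc[0, 1] == pytest.approx(1.0)

    def test_matches_elementwise_bruteforce(self, rng):
        for _ in range(100):
            g = 10
            a = rng.uniform(0, 1, (g, g))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 1.0)
            d = tom_dissimilarity(a).to_numpy()
            oracle = tom_bruteforce(a)
            assert np.max(np.abs(d - oracle)) < 1e-10

    def test_range_and_symmetry(self, rng):
        a = rng.uniform(0, 1, (15, 15))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        d = tom_dissimilarity(a).to_numpy()
        assert np.allclose(d, d.T)
        assert d.min() >= 0 and d.max() <= 1
        assert np.allclose(np.diag(d), 0.0)


def _orthogonal_block_expression(sizes=(40, 40), n=8):
    # exact within-block correlation 1, between-block correlation 0
    base = np.zeros((2, n))
    base[0, : n // 2] = 1.0
    base[0, n // 2 :] = -1.0
    base[1] = np.tile([1.0, -1.0], n // 2)
    rows, genes, labels = [], [], []
    for b, size in enumerate(sizes):
        for i in range(size):
            rows.append(base[b] * (i + 1))  # scaled copies: correlation 1
            genes.append(f"b{b}_{i}")
            labels.append(b + 1)
    return make_expression(np.vstack(rows), genes=genes), pd.Series(labels, index=genes)


class TestDetectModules:
    def test_two_exact_blocks_recovered_perfectly(self):
        expr, truth = _orthogonal_block_expression()
        dis = tom_dissimilarity(signed_adjacency(expr, beta=6))
        mods = detect_modules(dis, min_module_size=30)
        assert set(mods.labels.unique()) == {1, 2}
        for m in (1, 2):
            blocks = truth[mods.labels == m].unique()
            assert len(blocks) == 1

    def test_few_uncorrelated_genes_all_unassigned(self, rng):
        expr = make_expression(rng.normal(size=(10, 30)))
        dis = tom_dissimilarity(signed_adjacency(expr, beta=6))
        with pytest.warns(UserWarning, match="unassigned"):
            mods = detect_modules(dis, min_module_size=30)
        assert (mods.labels == 0).all()

    def test_gene_order_permutation_invariant_up_to_renaming(self):
        expr, _, _ = simulate_module_expression(seed=1)
        dis = tom_dissimilarity(signed_adjacency(expr, beta=10))
        mods = detect_modules(dis, min_module_size=30)
        rng = np.random.default_rng(3)
        perm = rng.permutation(len(dis))
        dis_p = dis.iloc[perm, perm]
        mods_p = detect_modules(dis_p, min_module_size=30)
        # same partition of genes
        def partition(labels):
            out = {}
            for g, m in labels.items():
                out.setdefault(m, set()).add(g)
            return {frozenset(v) for k, v in out.items() if k != 0}
        assert partition(mods.labels) == partition(mods_p.labels)

    def test_correlated_module_pair_merged(self):
        # two blocks driven by the same latent must merge into one module
        rng = np.random.default_rng(5)
        n = 60
        latent = rng.normal(size=n)
        rows = []
        for i in range(70):
            rows.append(np.sqrt(0.8) * latent + np.sqrt(0.2) * rng.normal(size=n))
        expr = make_expression(np.vstack(rows))
        dis = tom_dissimilarity(signed_adjacency(expr, beta=10))
        mods = detect_modules(dis, min_module_size=30, expr=expr, merge_threshold=0.25)
        assert len(mods.module_ids) == 1


class TestModuleEigengenes:
    def test_identical_genes_have_unit_kme(self):
        x = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.0])
        expr = make_expression(np.vstack([x] * 4))
        labels = pd.Series([1] * 4, index=expr.gene_ids)
        from tfnet.coexpress import _as_modules

        eig = module_eigengenes(expr, _as_modules(labels))
        assert np.allclose(eig.kme.to_numpy(), 1.0)
        assert eig.hub.all()

    def test_flipping_all_genes_flips_eigengene(self, rng):
        vals = rng.normal(size=(6, 10))
        expr = make_expression(vals)
        flipped = make_expression(-vals)
        labels = pd.Series([1] * 6, index=expr.gene_ids)
        from tfnet.coexpress import _as_modules

        e1 = module_eigengenes(expr, _as_modules(labels)).eigengenes[1]
        e2 = module_eigengenes(flipped, _as_modules(labels)).eigengenes[1]
        assert np.allclose(e1.to_numpy(), -e2.to_numpy(), atol=1e-10)

    def test_eigengene_maximizes_explained_variance(self, rng):
        vals = rng.normal(size=(8, 12))
        expr = make_expression(vals)
        labels = pd.Series([1] * 8, index=expr.gene_ids)
        from tfnet.coexpress import _as_modules

        v = module_eigengenes(expr, _as_modules(labels)).eigengenes[1].to_numpy()
        xz = (vals - vals.mean(1, keepdims=True)) / vals.std(1, keepdims=True)
        var_eig = np.sum((xz @ v) ** 2)
        top_eigenvalue = np.linalg.eigvalsh(xz.T @ xz).max()
        assert var_eig == pytest.approx(top_eigenvalue, rel=1e-9)
        for _ in range(20):
            u = rng.normal(size=len(v))
            u /= np.linalg.norm(u)
            assert np.sum((xz @ u) ** 2) <= var_eig + 1e-9

    def test_singleton_module_uses_standardized_profile(self, rng):
        vals = rng.normal(size=(1, 8))
        expr = make_expression(vals)
        labels = pd.Series([1], index=expr.gene_ids)
        from tfnet.coexpress import _as_modules

        eig = module_eigengenes(expr, _as_modules(labels)).eigengenes[1].to_numpy()
        z = (vals[0] - vals[0].mean()) / vals[0].std()
        z /= np.linalg.norm(z)
        assert np.allclose(np.abs(eig), np.abs(z), atol=1e-10)


class TestTraitAssociation:
    def test_display_statistic_formula(self, rng):
        expr, labels, trait = simulate_module_expression(
            seed=3, trait_effects={1: 2.0}
        )
        dis = tom_dissimilarity(signed_adjacency(expr, beta=10))
        mods = detect_modules(dis, min_module_size=30, expr=expr)
        assoc = module_trait_association(module_eigengenes(expr, mods), trait)
        for _, row in assoc.iterrows():
            expected = -np.sign(row["r"]) * np.log10(max(row["pvalue"], 1e-300))
            assert row["display_stat"] == pytest.approx(expected)

    def test_trait_equal_to_eigengene_is_maximal(self, rng):
        vals = rng.normal(size=(6, 12))
        expr = make_expression(vals)
        labels = pd.Series([1] * 6, index=expr.gene_ids)
        from tfnet.coexpress import _as_modules

        eig = module_eigengenes(expr, _as_modules(labels))
        assoc = module_trait_association(eig, eig.eigengenes[1])
        row = assoc.iloc[0]
        assert row["r"] == pytest.approx(1.0)
        assert row["significant"]

    def test_constant_trait_rejected(self, rng):
        vals = rng.normal(size=(4, 10))
        expr = make_expression(vals)
        labels = pd.Series([1] * 4, index=expr.gene_ids)
        from tfnet.coexpress import _as_modules

        eig = module_eigengenes(expr, _as_modules(labels))
        with pytest.raises(ValueError, match="constant trait"):
            module_trait_association(eig, np.ones(10))


class TestModuleOverlap:
    def test_closed_form_tail(self):
        universe = [f"u{i}" for i in range(20)]
        a = universe[:5]
        b = universe[2:5] + [universe[10]]
        res = module_overlap(a, b, universe)
        assert res.pvalue == pytest.approx(155 / 4845, rel=1e-12)
        assert res.pvalue == pytest.approx(
            hypergeom_tail_bruteforce(3, 5, 4, 20), rel=1e-12
        )

    def test_odds_ratio_cross_product(self):
        universe = [f"u{i}" for i in range(20)]
        a = universe[:5]
        b = universe[2:5] + [universe[10]]
        res = module_overlap(a, b, universe)
        assert res.odds_ratio == pytest.approx((3 * 14) / (2 * 1))

    def test_zero_overlap_gives_p_one(self):
        universe = [f"u{i}" for i in range(20)]
        res = module_overlap(universe[:5], universe[5:9], universe)
        assert res.pvalue == pytest.approx(1.0)

    def test_haldane_correction_only_when_needed(self):
        universe = [f"u{i}" for i in range(10)]
        res = module_overlap(universe[:5], universe[:5], universe)  # c cell = 0
        # a=5, b=0, c=0, d=5 -> all cells +0.5
        assert res.odds_ratio == pytest.approx((5.5 * 5.5) / (0.5 * 0.5))

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            module_overlap([], [], [])

    def test_bonferroni_scaling(self):
        universe = [f"u{i}" for i in range(20)]
        r1 = module_overlap(universe[:5], universe[2:6], universe, n_comparisons=1)
        r5 = module_overlap(universe[:5], universe[2:6], universe, n_comparisons=5)
        assert r5.adjusted_pvalue == pytest.approx(min(1.0, r1.pvalue * 5))


def test_regress_covariates_removes_linear_effect(rng):
    n = 30
    cov = pd.DataFrame({"batch": rng.normal(size=n)}, index=[f"s{i}" for i in range(n)])
    signal = rng.normal(size=(5, n))
    vals = signal + 3.0 * cov["batch"].to_numpy()[None, :]
    expr = make_expression(vals, samples=list(cov.index))
    resid = regress_covariates(expr, cov)
    for row in resid.values:
        r, _ = stats.pearsonr(row, cov["batch"])
        assert abs(r) < 1e-10
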