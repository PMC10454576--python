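import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from oracles import jacobi_eigh, pearson_loops
from saltpipe.coexpress import (build_adjacency, detect_modules, eigengene,
                                filter_expression, hub_genes, log_transform,
                                module_trait_correlation)
from saltpipe.io import ExpressionMatrix
from saltpipe.simulate import NetworkSpec, gen_expression


def make_expr(fpkm: np.ndarray, genes=None, samples=None, groups=None):
    genes = genes or [f"g{i}" for i in range(fpkm.shape[0])]
    samples = samples or [f"s{j}" for j in range(fpkm.shape[1])]
    groups = groups or ["grp"] * len(samples)
    return ExpressionMatrix(fpkm=pd.DataFrame(fpkm, index=genes, columns=samples),
                            groups=pd.Series(groups, index=samples))


class TestFilter:
    def test_low_expression_gene_removed(self):
        expr = make_expr(np.array([[4.9] * 6, [10.0] * 6]))
        kept = filter_expression(expr)
        assert list(kept.fpkm.index) == ["g1"]

    def test_zero_threshold_is_identity(self):
        expr = make_expr(np.random.default_rng(0).uniform(0, 3, (5, 6)))
        assert filter_expression(expr, fpkm_min=0).fpkm.equals(expr.fpkm)

    def test_deg_set_restriction_and_empty_error(self):
        expr = make_expr(np.full((3, 6), 10.0))
        kept = filter_expression(expr, deg_set={"g0", "g2"})
        assert list(kept.fpkm.index) == ["g0", "g2"]
        with pytest.raises(ValueError, match="empty"):
            filter_expression(expr, fpkm_min=100)


class TestAdjacency:
    def test_correlation_identities(self):
        s = np.arange(8, dtype=float)
        # cor = 1, cor = -1 and cor = -0.5 pairs on the log2 scale
        x = np.vstack([s, 2 * s + 1, -s + 10])
        expr = make_expr(2.0 ** x - 1.0)
        net = build_adjacency(expr, soft_power=12)
        assert net.adjacency.iloc[0, 1] == pytest.approx(1.0)
        assert net.adjacency.iloc[0, 2] == pytest.approx(1.0)  # |cor| = 1

    def test_half_correlation_power_twelve(self):
        # construct two log2 profiles with exact Pearson correlation -0.5
        a = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        b = np.array([-1.0, 0.0, 0.0, 1.0, -1.0, 1.0])
        b = b - b.mean()
        b = b - a * (a @ b) / (a @ a)          # orthogonalize
        mix = -0.5 * a / np.linalg.norm(a) * np.sqrt(len(a)) + \
            np.sqrt(1 - 0.25) * b / np.linalg.norm(b) * np.sqrt(len(b))
        assert np.corrcoef(a, mix)[0, 1] == pytest.approx(-0.5)
        # FPKM = 2^x - 1 so log2(FPKM + 1) returns x exactly; the +4 shift
        # keeps FPKM nonnegative and leaves the correlation unchanged
        expr = make_expr(2.0 ** np.vstack([a + 4.0, mix + 4.0]) - 1.0)
        x = log_transform(expr)
        assert np.corrcoef(x.values)[0, 1] == pytest.approx(-0.5, abs=1e-12)
        net = build_adjacency(expr, soft_power=12)
        assert net.adjacency.iloc[0, 1] == pytest.approx(0.000244140625, abs=1e-15)

    def test_bounds_symmetry_and_beta_monotonicity(self):
        expr, _ = gen_expression(NetworkSpec(seed=1))
        a6 = build_adjacency(expr, soft_power=6).adjacency.values
        a12 = build_adjacency(expr, soft_power=12).adjacency.values
        for a in (a6, a12):
            assert np.allclose(a, a.T)
            assert a.min() >= 0 and a.max() <= 1
            assert np.allclose(np.diag(a), 1)
        off = ~np.eye(len(a6), dtype=bool)
        assert (a12[off] <= a6[off] + 1e-12).all()


class TestModules:
    def test_planted_blocks_recovered_exactly_without_noise(self):
        expr, truth = gen_expression(NetworkSpec(seed=0, block_cor=1.0,
                                                 n_background=0))
        net = build_adjacency(expr)
        mods = detect_modules(net, expr)
        assert adjusted_rand_score(truth.loc[mods.assignments.index],
                                   mods.assignments) == pytest.approx(1.0)
        assert "grey" not in set(mods.assignments)

    def test_small_noise_clusters_all_grey(self):
        rng = np.random.default_rng(3)
        expr = make_expr(2.0 ** rng.normal(5, 1, (20, 10)))
        net = build_adjacency(expr)
        with pytest.warns(UserWarning, match="grey"):
            mods = detect_modules(net, expr, min_module_size=30)
        assert set(mods.assignments) == {"grey"}

    def test_identical_blocks_merged(self):
        # two blocks driven by the same latent factor -> ME correlation 1
        rng = np.random.default_rng(4)
        z = rng.normal(0, 1, 12)
        profiles = [z + rng.normal(0, 0.05, 12) for _ in range(60)]
        expr = make_expr(2.0 ** (np.array(profiles) + 5.0))
        net = build_adjacency(expr)
        mods = detect_modules(net, expr, min_module_size=20)
        non_grey = set(mods.assignments) - {"grey"}
        assert len(non_grey) == 1


class TestEigengene:
    def test_rank_one_block_tracks_common_profile(self):
        z = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 0.0])
        block = pd.DataFrame(np.vstack([z, 2 * z + 1, 0.5 * z]),
                             index=list("abc"),
                             columns=[f"s{j}" for j in range(6)])
        me = eigengene(block)
        assert abs(np.corrcoef(me, z)[0, 1]) == pytest.approx(1.0)
        assert np.corrcoef(me, z)[0, 1] > 0        # orientation
        assert me.std(ddof=1) == pytest.approx(1.0)

    def test_orientation_is_deterministic_under_global_negation(self):
        rng = np.random.default_rng(8)
        block = pd.DataFrame(rng.normal(0, 1, (10, 8)))
        me = eigengene(block)
        me_again = eigengene(block.copy())
        assert np.allclose(me, me_again)

    def test_matches_jacobi_covariance_oracle(self):
        rng = np.random.default_rng(11)
        block = pd.DataFrame(rng.normal(0, 1, (30, 8)),
                             index=[f"g{i}" for i in range(30)],
                             columns=[f"s{j}" for j in range(8)])
        me = eigengene(block)
        z = block.sub(block.mean(axis=1), axis=0).div(block.std(axis=1, ddof=1), axis=0)
        # sample x sample second-moment matrix; PC1 by Jacobi rotations
        cov = (z.values.T @ z.values) / (30 - 1)
        _, vecs = jacobi_eigh(cov)
        pc1 = vecs[:, 0]
        assert abs(pearson_loops(list(me.values), list(pc1))) == pytest.approx(
            1.0, abs=1e-9)

    def test_constant_block_rejected(self):
        block = pd.DataFrame(np.ones((3, 5)))
        with pytest.raises(ValueError):
            eigengene(block)


class TestModuleTrait:
    def test_group_tracking_module_selected(self):
        expr, _ = gen_expression(NetworkSpec(seed=5))
        net = build_adjacency(expr)
        mods = detect_modules(net, expr)
        mt = module_trait_correlation(mods, expr.groups)
        hits = mt[mt.selected]
        assert ("M1", "NY2-24") in set(zip(hits.module, hits.group))

    def test_pearson_matches_loop_formula(self):
        me = pd.DataFrame({"M1": [2.0, 1.0, -1.0, 0.5, -0.5, 1.5, -2.0, 0.0]},
                          index=[f"s{j}" for j in range(8)])
        groups = pd.Series(["a"] * 4 + ["b"] * 4, index=me.index)
        from saltpipe.coexpress import ModuleSet
        mods = ModuleSet(assignments=pd.Series("M1", index=["g"]), eigengenes=me)
        mt = module_trait_correlation(mods, groups).set_index("group")
        indicator = [1.0] * 4 + [0.0] * 4
        assert mt.at["a", "r"] == pytest.approx(
            pearson_loops(list(me["M1"]), indicator))

    def test_small_group_excluded_with_warning(self):
        me = pd.DataFrame({"M1": np.arange(5.0)}, index=[f"s{j}" for j in range(5)])
        groups = pd.Series(["a", "a", "a", "a", "lonely"], index=me.index)
        from saltpipe.coexpress import ModuleSet
        mods = ModuleSet(assignments=pd.Series("M1", index=["g"]), eigengenes=me)
        with pytest.warns(UserWarning, match="lonely"):
            mt = module_trait_correlation(mods, groups)
        assert "lonely" not in set(mt.group)


class TestHubs:
    def test_star_topology_center_is_hub(self):
        rng = np.random.default_rng(6)
        center = rng.normal(0, 1, 12)
        spokes = [0.7 * center + 0.3 * rng.normal(0, 1, 12) for _ in range(6)]
        expr = make_expr(2.0 ** (np.vstack([center] + spokes) + 5.0))
        net = build_adjacency(expr, soft_power=6)
        from saltpipe.coexpress import ModuleSet
        mods = ModuleSet(assignments=pd.Series("M1", index=expr.fpkm.index),
                         eigengenes=pd.DataFrame())
        hubs, edges = hub_genes(net, mods)
        assert hubs.at[0, "hub"] == "g0"
        assert (edges.groupby("source").size() <= 5).all()

    def test_hub_matches_rowsum_oracle(self):
        expr, _ = gen_expression(NetworkSpec(seed=9))
        net = build_adjacency(expr)
        mods = detect_modules(net, expr)
        hubs, _ = hub_genes(net, mods)
        for _, row in hubs.iterrows():
            members = sorted(mods.assignments.index[mods.assignments == row.module])
            sums = {}
            for g in members:
                sums[g] = sum(net.adjacency.at[g, h] for h in members if h != g)
            best = max(sums.values())
            expected = min(g for g, s in sums.items() if s == best)
            assert row.hub == expected

    def test_tie_broken_by_gene_id(self):
        # identical genes: all connectivities equal, first id wins
        profile = np.array([1.0, 2, 3, 4, 5, 6])
        expr = make_expr(2.0 ** (np.vstack([profile] * 4) + 5.0))
        net = build_adjacency(expr)
        from saltpipe.coexpress import ModuleSet
        mods = ModuleSet(assignments=pd.Series("M1", index=expr.fpkm.index),
                         eigengenes=pd.DataFrame())
        hubs, _ = hub_genes(net, mods)
        assert hubs.at[0, "hub"] == "g0"
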