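"""DEG filtering, BH, coexpression modules, eigengenes, associations, RV."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from vagimics.integration import (
    CoexpressionNetwork,
    associate_microbes,
    benjamini_hochberg,
    coexpression_network,
    compute_eigengenes,
    filter_degs,
    louvain_partition,
    module_eigengene,
    pearson_r_p,
    rv_coefficient,
)
from vagimics.simulate import SimulationConfig, simulate_expression, simulate_otu_study
from tests.conftest import relative


class TestFilterDegs:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "log2fc", "fdr"])

    def test_worked_rank_value(self):
        out = filter_degs(self._table([("g1", 2.0, 0.01)]))
        assert len(out) == 1
        assert out.loc[0, "direction"] == "up"
        assert out.loc[0, "rank_value"] == pytest.approx(4.0)

    def test_fold_change_filter(self):
        out = filter_degs(self._table([("g1", 0.9, 0.04)]))
        assert len(out) == 0

    def test_counts_under_joint_filter(self):
        rows = [
            ("g1", 2.0, 0.01),   # pass
            ("g2", -1.5, 0.04),  # pass, down
            ("g3", 1.2, 0.001),  # pass
            ("g4", 0.5, 0.001),  # fc fail
            ("g5", 3.0, 0.2),    # fdr fail
            ("g6", -0.2, 0.9),   # both fail
        ]
        out = filter_degs(self._table(rows))
        assert sorted(out["gene_id"]) == ["g1", "g2", "g3"]
        assert out.set_index("gene_id")["direction"].to_dict() == {
            "g1": "up", "g2": "down", "g3": "up"
        }

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            filter_degs(pd.DataFrame({"gene_id": ["g"], "log2fc": [1.0]}))


class TestBenjaminiHochberg:
    def test_worked_step_up_vector(self):
        out = benjamini_hochberg([0.01, 0.02, 0.04, 0.05])
        assert np.allclose(out, [0.04, 0.04, 0.05, 0.05])

    def test_boundary_and_single(self):
        assert np.allclose(benjamini_hochberg([1.0, 1.0, 1.0]), 1.0)
        assert benjamini_hochberg([0.3])[0] == pytest.approx(0.3)

    def test_monotone_after_sorting_by_raw_p(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=50)
        adj = benjamini_hochberg(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.2])


class TestPearson:
    def test_perfect_correlations(self):
        r, p = pearson_r_p([1, 2, 3], [1, 2, 3])
        assert r == pytest.approx(1.0) and p == pytest.approx(0.0)
        r, _ = pearson_r_p([1, 2, 3], [3, 2, 1])
        assert r == pytest.approx(-1.0)

    def test_zero_variance_flagged(self):
        r, p = pearson_r_p([1, 1, 1], [1, 2, 3])
        assert np.isnan(r) and np.isnan(p)

    def test_p_matches_permutation_oracle(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(10)
        y = 0.5 * x + rng.standard_normal(10)
        r_obs, p = pearson_r_p(x, y)
        perms = np.stack([rng.permutation(y) for _ in range(100_000)])
        xc = (x - x.mean()) / x.std()
        pc = (perms - perms.mean(axis=1, keepdims=True)) / perms.std(axis=1, keepdims=True)
        r_null = pc @ xc / 10
        p_perm = np.mean(np.abs(r_null) >= abs(r_obs))
        assert abs(p - p_perm) < 0.02


class TestCoexpressionNetwork:
    def test_identical_pair_single_edge(self):
        rng = np.random.default_rng(2)
        prof = rng.standard_normal(6)
        expr = pd.DataFrame(
            [prof, prof, rng.standard_normal(6)],
            index=["g1", "g2", "g3"],
            columns=[f"s{i}" for i in range(6)],
        )
        net = coexpression_network(expr)
        assert len(net.edges) == 1
        assert set(net.genes) == {"g1", "g2"}

    def test_no_filtering_gives_complete_graph(self):
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(
            rng.standard_normal((5, 6)),
            index=[f"g{i}" for i in range(5)],
            columns=[f"s{i}" for i in range(6)],
        )
        net = coexpression_network(expr, r_threshold=0.0, p_threshold=1.01)
        assert len(net.edges) == 10

    def test_constant_gene_skipped_with_warning(self):
        expr = pd.DataFrame(
            [[1.0] * 5, [1, 2, 3, 4, 5], [5, 4, 3, 1, 2]],
            index=["flat", "g1", "g2"],
            columns=[f"s{i}" for i in range(5)],
        )
        with pytest.warns(UserWarning, match="constant"):
            net = coexpression_network(expr, r_threshold=0.1, p_threshold=1.0)
        assert "flat" not in net.genes

    def test_within_module_density_exceeds_between(self):
        cfg = SimulationConfig(seed=4, n_expression_per_stage=3)
        study = simulate_otu_study(cfg)
        expr, deg, truth = simulate_expression(cfg, study.otu_table)
        log_expr = np.log2(expr + 1)
        module_of = truth["module_of_gene"]
        genes = list(module_of)
        net = coexpression_network(log_expr.loc[genes])
        edges = {frozenset((a, b)) for a, b in zip(net.edges["gene_i"], net.edges["gene_j"])}
        within = between = 0
        n_within = n_between = 0
        for a, b in itertools.combinations(genes, 2):
            same = module_of[a] == module_of[b]
            hit = frozenset((a, b)) in edges
            if same:
                n_within += 1
                within += hit
            else:
                n_between += 1
                between += hit
        assert within / n_within > between / n_between

    def test_edge_set_shrinks_with_r_threshold(self):
        rng = np.random.default_rng(5)
        expr = pd.DataFrame(
            rng.standard_normal((8, 10)),
            index=[f"g{i}" for i in range(8)],
            columns=[f"s{i}" for i in range(10)],
        )
        n_loose = len(coexpression_network(expr, 0.1, 1.0).edges)
        n_tight = len(coexpression_network(expr, 0.6, 1.0).edges)
        assert n_tight <= n_loose


def _modularity_bruteforce(g: nx.Graph) -> float:
    """Best modularity over every partition of the nodes (Bell-number search)."""
    nodes = list(g.nodes)

    def partitions(items):
        if not items:
            yield []
            return
        first, rest = items[0], items[1:]
        for part in partitions(rest):
            for i in range(len(part)):
                yield part[:i] + [[first] + part[i]] + part[i + 1:]
            yield [[first]] + part

    return max(
        nx.community.modularity(g, [set(b) for b in part], weight="weight")
        for part in partitions(nodes)
    )


class TestLouvain:
    def _net_from_graph(self, g):
        edges = pd.DataFrame(
            [(a, b, 1.0, 0.0) for a, b in g.edges],
            columns=["gene_i", "gene_j", "r", "p"],
        )
        return CoexpressionNetwork(list(g.nodes), edges, 0.5, 0.05)

    def test_disconnected_cliques(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        g = nx.relabel_nodes(g, {i: f"g{i}" for i in g.nodes})
        part = louvain_partition(self._net_from_graph(g), seed=0)
        assert part.n_modules == 2
        assert {frozenset(part.genes_of(1)), frozenset(part.genes_of(2))} == {
            frozenset(f"g{i}" for i in range(5)),
            frozenset(f"g{i}" for i in range(5, 10)),
        }

    def test_matches_bruteforce_optimum_on_toy_graph(self):
        g = nx.Graph()
        g.add_edges_from(
            [("a", "b"), ("b", "c"), ("a", "c"), ("d", "e"), ("e", "f"), ("d", "f"), ("c", "d"), ("g", "h")]
        )
        nx.set_edge_attributes(g, 1.0, "weight")
        part = louvain_partition(self._net_from_graph(g), seed=0)
        assert part.modularity == pytest.approx(_modularity_bruteforce(g), abs=1e-9)

    def test_single_edge_graph(self):
        g = nx.Graph([("a", "b")])
        nx.set_edge_attributes(g, 1.0, "weight")
        part = louvain_partition(self._net_from_graph(g), seed=0)
        communities = [set(part.genes_of(m)) for m in range(1, part.n_modules + 1)]
        assert part.modularity == pytest.approx(
            nx.community.modularity(g, communities, weight="weight")
        )

    def test_empty_network_rejected(self):
        net = CoexpressionNetwork([], pd.DataFrame(columns=["gene_i", "gene_j", "r", "p"]), 0.9, 0.05)
        with pytest.raises(ValueError):
            louvain_partition(net, seed=0)


class TestModuleEigengene:
    def test_identical_genes_rank_one(self):
        prof = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.0])
        expr = pd.DataFrame([prof, prof, prof], index=["a", "b", "c"],
                            columns=[f"s{i}" for i in range(6)])
        scores, ve = module_eigengene(expr, ["a", "b", "c"])
        z = (prof - prof.mean()) / prof.std()
        assert np.allclose(scores.to_numpy(), z, atol=1e-9)
        assert ve == pytest.approx(1.0)

    def test_sign_convention_and_gene_order_invariance(self):
        rng = np.random.default_rng(6)
        factor = rng.standard_normal(8)
        expr = pd.DataFrame(
            [0.9 * factor + rng.normal(0, 0.3, 8) for _ in range(6)],
            index=[f"g{i}" for i in range(6)],
            columns=[f"s{i}" for i in range(8)],
        )
        scores, _ = module_eigengene(expr, [f"g{i}" for i in range(6)])
        mean_profile = ((expr.T - expr.mean(axis=1)) / expr.std(axis=1, ddof=0)).mean(axis=1)
        assert np.corrcoef(scores, mean_profile)[0, 1] >= 0
        reordered, _ = module_eigengene(expr, [f"g{i}" for i in (3, 1, 5, 0, 4, 2)])
        assert np.allclose(scores.to_numpy(), reordered.to_numpy(), atol=1e-9)

    def test_planted_factor_recovery(self):
        rng = np.random.default_rng(7)
        factor = rng.standard_normal(12)
        expr = pd.DataFrame(
            [0.9 * factor + rng.normal(0, 0.3, 12) for _ in range(20)],
            index=[f"g{i}" for i in range(20)],
            columns=[f"s{i}" for i in range(12)],
        )
        scores, ve = module_eigengene(expr, list(expr.index))
        assert abs(np.corrcoef(scores, factor)[0, 1]) >= 0.9

    def test_constant_module_rejected(self):
        expr = pd.DataFrame([[1.0] * 4, [2.0] * 4], index=["a", "b"],
                            columns=[f"s{i}" for i in range(4)])
        with pytest.raises(ValueError):
            module_eigengene(expr, ["a", "b"])


class TestAssociateMicrobes:
    def _eigengenes(self, scores: pd.DataFrame):
        from vagimics.integration import EigengeneSet

        return EigengeneSet(scores=scores, variance_explained={})

    def test_self_correlation(self):
        rng = np.random.default_rng(8)
        v = rng.dirichlet(np.ones(3), size=6)
        tab = relative(v)
        scores = pd.DataFrame({1: v[:, 0]}, index=tab.sample_ids)
        out = associate_microbes(tab, self._eigengenes(scores))
        row = out[(out["otu_id"] == "OTU_1") & (out["module"] == 1)].iloc[0]
        assert row["r"] == pytest.approx(1.0)

    def test_sample_mismatch_lists_ids(self):
        rng = np.random.default_rng(9)
        tab = relative(rng.dirichlet(np.ones(3), size=4))
        scores = pd.DataFrame({1: np.zeros(4)}, index=["x1", "x2", "s1", "s2"])
        with pytest.raises(ValueError, match="x1"):
            associate_microbes(tab, self._eigengenes(scores))

    def test_planted_coupling_detected(self):
        sps = {"C9": 4, "P9": 6, "P12": 4, "P16": 4, "P21": 4, "P28": 6, "P35": 2}
        hits = 0
        for seed in range(5):
            cfg = SimulationConfig(
                seed=seed, depth=("fixed", 5000),
                samples_per_stage=sps, n_expression_per_stage=6,
            )
            study = simulate_otu_study(cfg)
            expr, deg, truth = simulate_expression(cfg, study.otu_table)
            degs = filter_degs(deg)
            log_expr = np.log2(expr.loc[expr.index.intersection(degs["gene_id"])] + 1)
            net = coexpression_network(log_expr)
            part = louvain_partition(net, seed=seed)
            eg = compute_eigengenes(log_expr, part)
            otu_ids = [f"OTU_{j + 1}" for j in range(10)]
            idx = [study.otu_table.sample_ids.index(s) for s in truth["expression_samples"]]
            vals = study.otu_table.counts[idx][:, :10].astype(float)
            vals /= vals.sum(axis=1, keepdims=True)
            tab = relative(vals)
            tab.sample_ids = truth["expression_samples"]
            tab.otu_ids = otu_ids
            scores = eg.scores.copy()
            scores.index = truth["expression_samples"]
            out = associate_microbes(tab, self._eigengenes(scores))
            sig = out[out["significant"]]
            hits += (sig["otu_id"] == truth["couplings"][1]).any()
        assert hits >= 4


class TestRvCoefficient:
    def test_identity_and_scale_invariance(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal((8, 5))
        assert rv_coefficient(x, x, n_permutations=9, seed=0).rv == pytest.approx(1.0)
        assert rv_coefficient(x, 3 * x, n_permutations=9, seed=0).rv == pytest.approx(1.0)

    def test_p_uses_add_one_rule(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal((10, 4))
        res = rv_coefficient(x, x + rng.normal(0, 0.01, x.shape), n_permutations=99, seed=0)
        assert res.p_perm == pytest.approx(1 / 100)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            rv_coefficient(np.zeros((2, 3)), np.zeros((2, 3)), seed=0)
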