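import numpy as np
import pandas as pd
import pytest

from mmuphin.continuous import (
    ContinuousStructureError,
    SignInconsistencyError,
    assign_scores,
    build_pc_network,
    consensus_loading,
    cosine_similarity,
    detect_modules,
    discover_gradients,
    pca_top_loadings,
    threshold_sweep,
    validate_consensus,
    PCLoadingSet,
)
from mmuphin.data_model import FeatureTable, tss_normalize, arcsin_sqrt_transform


def _factor_table(rng, n=60, P=30, ids=None, factor=None, noise=0.01, prefix="s"):
    """Counts whose transformed profile follows a 1-factor model."""
    if factor is None:
        factor = rng.uniform(-1, 1, n)
    direction = rng.normal(0, 1, P)
    direction /= np.linalg.norm(direction)
    base = rng.uniform(2, 4, P)
    transformed = base[None, :] + 0.3 * np.outer(factor, direction) \
        + rng.normal(0, noise, (n, P))
    counts = np.exp(transformed)
    ids = ids or [f"{prefix}{i}" for i in range(n)]
    table = FeatureTable(pd.DataFrame(counts, index=ids,
                                      columns=[f"f{j}" for j in range(P)]))
    return table, factor, direction


class TestPcaTopLoadings:
    def test_one_factor_model_aligns_first_loading(self, rng):
        table, factor, direction = _factor_table(rng, noise=0.005)
        ls = pca_top_loadings(table, threshold_v=0.5, study_id="A")
        # the TSS + arcsin-sqrt transform warps the planted direction a
        # little, but the factor itself must be recovered almost exactly
        assert abs(cosine_similarity(ls.loadings[0], direction)) > 0.85
        X = arcsin_sqrt_transform(tss_normalize(table))
        scores = (X - X.mean(axis=0)) @ ls.loadings[0]
        assert abs(np.corrcoef(scores, factor)[0, 1]) > 0.99

    def test_loadings_are_orthonormal(self, rng):
        table, *_ = _factor_table(rng, noise=0.3)
        ls = pca_top_loadings(table, threshold_v=0.9)
        G = ls.loadings @ ls.loadings.T
        np.testing.assert_allclose(G, np.eye(len(G)), atol=1e-10)

    def test_threshold_one_returns_full_rank(self, rng):
        table, *_ = _factor_table(rng, n=10, P=6, noise=0.5)
        ls = pca_top_loadings(table, threshold_v=1.0)
        assert ls.n_components == 6  # rank of a centered 10x6 matrix

    def test_cumulative_variance_rule(self, rng):
        table, *_ = _factor_table(rng, noise=0.3)
        ls = pca_top_loadings(table, threshold_v=0.8)
        cum = np.cumsum(ls.var_explained)
        assert cum[-1] >= 0.8
        assert ls.n_components == 1 or cum[-2] < 0.8

    def test_constant_table_rejected(self):
        t = FeatureTable(pd.DataFrame(np.full((5, 3), 2.0),
                                      index=list("abcde"), columns=["x", "y", "z"]))
        with pytest.raises(ContinuousStructureError):
            pca_top_loadings(t)


class TestCosine:
    @pytest.mark.parametrize("u,v,expected", [
        ([1, 0], [1, 0], 1.0),
        ([1, 0], [0, 1], 0.0),
        ([1, 2], [-1, -2], -1.0),
    ])
    def test_known_values(self, u, v, expected):
        assert cosine_similarity(np.array(u, float), np.array(v, float)) == \
            pytest.approx(expected, abs=1e-12)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity(np.zeros(3), np.ones(3))


def _loading_set(study, vectors, features=None):
    mat = np.array(vectors, float)
    mat = mat / np.linalg.norm(mat, axis=1, keepdims=True)
    features = features or [f"f{j}" for j in range(mat.shape[1])]
    var = np.linspace(0.5, 0.1, len(mat))
    return PCLoadingSet(study, mat, var / var.sum() * 0.9, list(features))


class TestPcNetwork:
    def test_twin_studies_match_with_weight_one(self, rng):
        w = rng.normal(0, 1, (3, 20))
        net = build_pc_network([_loading_set("A", w), _loading_set("B", w)], 0.7)
        for j in range(3):
            assert net.has_edge(("A", j + 1), ("B", j + 1))
            assert net[("A", j + 1)][("B", j + 1)]["weight"] == pytest.approx(1.0)
        # no within-study edges ever
        assert all(u[0] != v[0] for u, v in net.edges)

    def test_random_high_dim_loadings_have_no_edges(self, rng):
        a = _loading_set("A", rng.normal(0, 1, (4, 1000)))
        b = _loading_set("B", rng.normal(0, 1, (4, 1000)))
        net = build_pc_network([a, b], 0.7)
        assert net.number_of_edges() == 0

    def test_lower_threshold_only_adds_edges(self, rng):
        sets = [_loading_set(s, rng.normal(0, 1, (4, 8))) for s in "ABC"]
        hi = build_pc_network(sets, 0.8)
        lo = build_pc_network(sets, 0.5)
        assert set(hi.edges) <= set(lo.edges)

    def test_feature_alignment_by_intersection(self, rng):
        w = rng.normal(0, 1, (2, 10))
        a = _loading_set("A", w, features=[f"f{j}" for j in range(10)])
        b = _loading_set("B", w[:, :8], features=[f"f{j}" for j in range(8)])
        with pytest.warns(UserWarning, match="alignment"):
            net = build_pc_network([a, b], 0.5)
        assert len(net.graph["feature_ids"]) == 8

    def test_disjoint_features_rejected(self, rng):
        a = _loading_set("A", rng.normal(0, 1, (2, 5)), features=list("abcde"))
        b = _loading_set("B", rng.normal(0, 1, (2, 5)), features=list("vwxyz"))
        with pytest.raises(ContinuousStructureError):
            build_pc_network([a, b], 0.5)


class TestModulesAndConsensus:
    def _clique_network(self, rng):
        u = rng.normal(0, 1, 30)
        v = rng.normal(0, 1, 30)
        v -= u * (u @ v) / (u @ u)  # orthogonal gradients
        sets = []
        for s in "ABC":
            w1 = u + rng.normal(0, 0.05, 30)
            w2 = v + rng.normal(0, 0.05, 30)
            sets.append(_loading_set(s, [w1, w2]))
        return build_pc_network(sets, 0.7)

    def test_two_cliques_become_two_modules(self, rng):
        net = self._clique_network(rng)
        modules = detect_modules(net)
        assert len(modules) == 2
        assert {frozenset(m) for m in modules} == {
            frozenset({("A", 1), ("B", 1), ("C", 1)}),
            frozenset({("A", 2), ("B", 2), ("C", 2)}),
        }

    def test_singletons_dropped_and_empty_network(self, rng):
        net = self._clique_network(rng)
        net.add_node(("D", 1), study="D", pc=1)
        modules = detect_modules(net)
        assert all(("D", 1) not in m for m in modules)
        import networkx as nx
        assert detect_modules(nx.Graph()) == []

    def test_consensus_of_sign_flipped_members_is_anchor(self, rng):
        w = rng.normal(0, 1, 12)
        w /= np.linalg.norm(w)
        net = build_pc_network([_loading_set("A", [w]), _loading_set("B", [-w])], 0.5)
        c = consensus_loading([("A", 1), ("B", 1)], net)
        np.testing.assert_allclose(c.loading, w, atol=1e-12)
        assert c.signs[("A", 1)] == 1 and c.signs[("B", 1)] == -1

    def test_frustrated_triple_raises_inconsistency(self):
        # pairwise cosines (+, +, -): no sign assignment fixes it
        a = np.array([1.0, 0.0, 0.2])
        b = np.array([0.0, 1.0, 0.2])
        c = np.array([1.0, -1.0, 0.0])  # cos(a,c) > 0, cos(b,c) < 0
        import networkx as nx
        g = nx.Graph()
        g.graph["feature_ids"] = ["f0", "f1", "f2"]
        vecs = {("A", 1): a / np.linalg.norm(a), ("B", 1): b / np.linalg.norm(b),
                ("C", 1): c / np.linalg.norm(c)}
        g.graph["loadings"] = vecs
        g.add_nodes_from(vecs)
        with pytest.raises(SignInconsistencyError):
            consensus_loading(list(vecs), g)

    def test_unit_norm_flag(self, rng):
        w1 = rng.normal(0, 1, 10)
        w2 = w1 + rng.normal(0, 0.1, 10)
        net = build_pc_network([_loading_set("A", [w1]), _loading_set("B", [w2])], 0.5)
        c = consensus_loading([("A", 1), ("B", 1)], net, unit_norm=True)
        assert np.linalg.norm(c.loading) == pytest.approx(1.0)


class TestScoresAndValidation:
    def test_scores_reproduce_pc1_sample_scores(self, rng):
        table, *_ = _factor_table(rng)
        ls = pca_top_loadings(table, threshold_v=0.5, study_id="A")
        scores = assign_scores(table, ls.loadings[0], table.feature_ids)
        X = arcsin_sqrt_transform(tss_normalize(table))
        X = X - X.mean(axis=0, keepdims=True)
        expected = X @ ls.loadings[0]
        assert abs(np.corrcoef(scores, expected)[0, 1]) == pytest.approx(1.0, abs=1e-10)

    def test_validation_against_self_and_permuted_control(self, rng):
        table, factor, _ = _factor_table(rng, n=80)
        out, _ = discover_gradients({"A": table.select_samples(table.sample_ids[:40]),
                                     "B": table.select_samples(table.sample_ids[40:])},
                                    threshold_v=0.5, threshold_s=0.7)
        assert out, "expected at least one consensus module"
        best, ok = validate_consensus(out[0], table)
        assert ok and best > 0.9
        perm = table.values.copy()
        rng2 = np.random.default_rng(0)
        for i in range(len(perm)):  # feature-permute each sample profile
            perm[i] = perm[i, rng2.permutation(perm.shape[1])]
        worst, bad_ok = validate_consensus(out[0], table.with_values(perm))
        assert not bad_ok

    def test_score_recovers_planted_gradient(self, rng):
        factor = rng.uniform(-1, 1, 120)
        table, _, _ = _factor_table(rng, n=120, factor=factor)
        studies = {"A": table.select_samples(table.sample_ids[:60]),
                   "B": table.select_samples(table.sample_ids[60:])}
        out, _ = discover_gradients(studies, threshold_v=0.5, threshold_s=0.7)
        scores = assign_scores(table, out[0])
        assert abs(np.corrcoef(scores, factor)[0, 1]) > 0.95

    def test_threshold_sweep_monotone_edges(self, rng):
        table, factor, _ = _factor_table(rng, n=80, noise=0.2)
        studies = {"A": table.select_samples(table.sample_ids[:40]),
                   "B": table.select_samples(table.sample_ids[40:])}
        sweep = threshold_sweep(studies, thresholds=(0.5, 0.7, 0.8))
        edges = sweep.sort_values("threshold_s").n_edges.to_numpy()
        assert (np.diff(edges) <= 0).all()
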