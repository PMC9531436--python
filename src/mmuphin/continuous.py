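"""Continuous population-structure discovery via consensus PCA loadings.

Per study, PCA is run on centered arcsin-sqrt-transformed relative
abundances and the top loading vectors jointly explaining a target fraction
of variance are kept.  Loadings from different studies are connected in a
network when their absolute cosine similarity exceeds a threshold; densely
connected modules found by modularity clustering correspond to feature
covariation gradients that recur across studies.  Each module's
sign-corrected average loading is its consensus vector, which assigns a
continuous score to any sample by dot product with its centered transformed
profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from mmuphin.data_model import FeatureTable, arcsin_sqrt_transform, tss_normalize


class ContinuousStructureError(ValueError):
    pass


class SignInconsistencyError(ContinuousStructureError):
    """A module admits no sign assignment with all pairwise cosines positive.

    Raised during consensus construction; a higher cosine threshold for the
    loading network is recommended, which yields smaller, consistent modules.
    """


def _transformed(table: FeatureTable) -> np.ndarray:
    rel = table if table.is_relative else tss_normalize(table)
    return arcsin_sqrt_transform(rel)


@dataclass
class PCLoadingSet:
    """Top PCA loadings of one study (rows unit-norm, feature-aligned)."""

    study: str
    loadings: np.ndarray          # J x features
    var_explained: np.ndarray     # fraction per component
    feature_ids: list[str]

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]


def pca_top_loadings(
    table: FeatureTable,
    threshold_v: float = 0.80,
    study_id: str = "study",
) -> PCLoadingSet:
    """PCA of the centered, transformed table; keep the smallest set of top
    components whose cumulative variance explained reaches ``threshold_v``."""
    if table.shape[0] < 3:
        raise ContinuousStructureError("PCA needs at least 3 samples")
    X = _transformed(table)
    X = X - X.mean(axis=0, keepdims=True)
    if not np.any(X):
        raise ContinuousStructureError("constant table has no principal components")
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    var = s**2
    frac = var / var.sum()
    j = int(np.searchsorted(np.cumsum(frac), threshold_v - 1e-12) + 1)
    j = min(j, np.sum(var > var.sum() * 1e-12))
    return PCLoadingSet(study_id, vt[:j], frac[:j], table.feature_ids)


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine of the angle between two vectors, in [-1, 1]."""
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine undefined for zero vectors")
    return float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))


def build_pc_network(
    loading_sets: list[PCLoadingSet],
    threshold_s: float = 0.7,
) -> nx.Graph:
    """Network of cross-study PC loadings with |cosine| edge weights.

    Features are aligned by ID intersection (restricted loadings are
    re-normalized; the dropped fraction is reported via a warning).  Edges
    are kept only between PCs of different studies with
    ``|cos| > threshold_s``.
    """
    if len(loading_sets) < 2:
        raise ContinuousStructureError("need loading sets from at least 2 studies")
    shared = set(loading_sets[0].feature_ids)
    for ls in loading_sets[1:]:
        shared &= set(ls.feature_ids)
    if not shared:
        raise ContinuousStructureError("studies share no features")
    shared_ids = [f for f in loading_sets[0].feature_ids if f in shared]

    graph = nx.Graph()
    graph.graph["threshold_s"] = threshold_s
    graph.graph["feature_ids"] = shared_ids
    aligned: dict[tuple[str, int], np.ndarray] = {}
    for ls in loading_sets:
        pos = [ls.feature_ids.index(f) for f in shared_ids]
        dropped = 1 - len(pos) / len(ls.feature_ids)
        if dropped > 0:
            warnings.warn(f"study {ls.study!r}: {dropped:.1%} of loading mass features dropped "
                          "in cross-study alignment")
        for j in range(ls.n_components):
            w = ls.loadings[j, pos]
            norm = np.linalg.norm(w)
            if norm == 0:
                continue
            node = (ls.study, j + 1)
            aligned[node] = w / norm
            graph.add_node(node, study=ls.study, pc=j + 1,
                           var_explained=float(ls.var_explained[j]))
    nodes = sorted(aligned)
    for a_i, na in enumerate(nodes):
        for nb in nodes[a_i + 1:]:
            if na[0] == nb[0]:
                continue  # no within-study edges
            w = abs(float(np.dot(aligned[na], aligned[nb])))
            if w > threshold_s:
                graph.add_edge(na, nb, weight=w)
    graph.graph["loadings"] = aligned
    return graph


def detect_modules(graph: nx.Graph) -> list[list[tuple[str, int]]]:
    """Densely connected PC modules by greedy modularity maximization.

    Uses the deterministic agglomerative (Clauset-Newman-Moore) algorithm on
    edge weights; singleton communities are discarded.  Modules are ordered
    by size (descending), then lexicographically by members.
    """
    g = nx.Graph()
    g.add_nodes_from(sorted(graph.nodes))
    g.add_edges_from((u, v, d) for u, v, d in graph.edges(data=True))
    g.remove_nodes_from(list(nx.isolates(g)))
    if g.number_of_edges() == 0:
        return []
    comms = nx.community.greedy_modularity_communities(g, weight="weight")
    modules = [sorted(c) for c in comms if len(c) >= 2]
    modules.sort(key=lambda m: (-len(m), m))
    return modules


@dataclass
class ConsensusLoading:
    """Average of sign-corrected member loadings defining one gradient."""

    module_id: int
    members: list[tuple[str, int]]
    signs: dict[tuple[str, int], int]
    loading: np.ndarray
    feature_ids: list[str]
    mean_edge_weight: float = field(default=np.nan)


def consensus_loading(
    members: list[tuple[str, int]],
    graph: nx.Graph,
    module_id: int = 1,
    unit_norm: bool = False,
) -> ConsensusLoading:
    """Sign-correct a module's loadings and average them.

    The first member in (study, pc) order anchors the sign; every other
    member is flipped to have positive cosine with it.  If any pairwise
    cosine is still non-positive after flipping, the module is
    sign-inconsistent and :class:`SignInconsistencyError` is raised
    (a higher ``threshold_s`` is recommended).  The consensus is the plain
    arithmetic mean of corrected members; ``unit_norm=True`` rescales it to
    unit length.
    """
    if len(members) < 2:
        raise ContinuousStructureError("a module needs at least 2 members")
    loadings = graph.graph["loadings"]
    members = sorted(members)
    anchor = loadings[members[0]]
    signs: dict[tuple[str, int], int] = {}
    corrected = []
    for m in members:
        s = 1 if float(np.dot(anchor, loadings[m])) >= 0 else -1
        signs[m] = s
        corrected.append(s * loadings[m])
    mat = np.array(corrected)
    cos = mat @ mat.T
    off = cos[np.triu_indices(len(members), k=1)]
    if (off <= 0).any():
        raise SignInconsistencyError(
            "module members cannot be sign-aligned to all-positive pairwise "
            "cosines; rebuild the network with a higher cosine threshold"
        )
    consensus = mat.mean(axis=0)
    if unit_norm:
        consensus = consensus / np.linalg.norm(consensus)
    weights = [graph[u][v]["weight"] for u in members for v in members
               if u < v and graph.has_edge(u, v)]
    return ConsensusLoading(
        module_id=module_id, members=members, signs=signs, loading=consensus,
        feature_ids=list(graph.graph["feature_ids"]),
        mean_edge_weight=float(np.mean(weights)) if weights else np.nan,
    )


def assign_scores(table: FeatureTable, consensus: ConsensusLoading | np.ndarray,
                  feature_ids: list[str] | None = None) -> np.ndarray:
    """Per-sample continuous scores: centered transformed row . W_k."""
    if isinstance(consensus, ConsensusLoading):
        w, ids = consensus.loading, consensus.feature_ids
    else:
        w, ids = np.asarray(consensus, dtype=float), feature_ids
    X = _transformed(table)
    if ids is not None:
        pos = [table.feature_ids.index(f) for f in ids]
        X = X[:, pos]
    X = X - X.mean(axis=0, keepdims=True)
    return X @ w


def validate_consensus(
    consensus: ConsensusLoading,
    validation_table: FeatureTable,
    n_top_pcs: int = 3,
    threshold_s: float = 0.7,
) -> tuple[float, bool]:
    """Reproducibility of a consensus gradient in an external study.

    Computes the maximum absolute cosine between the consensus loading and
    the validation study's top ``n_top_pcs`` PC loadings (restricted to
    shared features); validated when it exceeds ``threshold_s``.
    """
    ls = pca_top_loadings(validation_table, threshold_v=1.0, study_id="validation")
    shared = [f for f in consensus.feature_ids if f in set(ls.feature_ids)]
    if not shared:
        raise ContinuousStructureError("no shared features with validation study")
    wpos = [consensus.feature_ids.index(f) for f in shared]
    vpos = [ls.feature_ids.index(f) for f in shared]
    w = consensus.loading[wpos]
    best = 0.0
    for j in range(min(n_top_pcs, ls.n_components)):
        v = ls.loadings[j, vpos]
        if np.linalg.norm(v) == 0 or np.linalg.norm(w) == 0:
            continue
        best = max(best, abs(cosine_similarity(w, v)))
    return best, best > threshold_s


def discover_gradients(
    tables: dict[str, FeatureTable],
    threshold_v: float = 0.80,
    threshold_s: float = 0.7,
    unit_norm: bool = False,
) -> tuple[list[ConsensusLoading], nx.Graph]:
    """End-to-end gradient discovery across studies.

    Returns consensus loadings ordered strongest first (module size, then
    mean internal edge weight) together with the PC network.
    """
    sets = [pca_top_loadings(t, threshold_v, study_id=s) for s, t in sorted(tables.items())]
    graph = build_pc_network(sets, threshold_s)
    modules = detect_modules(graph)
    out = []
    for m_id, members in enumerate(modules, start=1):
        out.append(consensus_loading(members, graph, module_id=m_id, unit_norm=unit_norm))
    out.sort(key=lambda c: (-len(c.members), -(c.mean_edge_weight if np.isfinite(c.mean_edge_weight) else 0.0)))
    return out, graph


def threshold_sweep(
    tables: dict[str, FeatureTable],
    thresholds: tuple[float, ...] = (0.5, 0.6, 0.7, 0.8),
    threshold_v: float = 0.80,
) -> pd.DataFrame:
    """Sensitivity of module structure to the cosine threshold."""
    rows = []
    sets = [pca_top_loadings(t, threshold_v, study_id=s) for s, t in sorted(tables.items())]
    for ts in thresholds:
        graph = build_pc_network(sets, ts)
        modules = detect_modules(graph)
        rows.append({
            "threshold_s": ts,
            "n_edges": graph.number_of_edges(),
            "n_modules": len(modules),
            "module_sizes": [len(m) for m in modules],
        })
    return pd.DataFrame(rows)
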