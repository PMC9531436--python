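"""Discrete population-structure discovery via PAM and prediction strength.

Partition-around-medoids (BUILD + SWAP) clustering on a community
dissimilarity matrix, evaluated by prediction strength within a study
(agreement between clusterings of random train/validation splits) and by
generalized prediction strength across studies (agreement between one
study's clustering and the classification of another study's samples to its
medoids).  A reproducible k-cluster structure yields prediction strength
near one; its absence leaves all k >= 2 low.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import calinski_harabasz_score, silhouette_score

from mmuphin.data_model import FeatureTable, dissimilarity


class ClusteringError(ValueError):
    pass


@dataclass
class ClusteringResult:
    k: int
    medoids: np.ndarray   # sample indices into the dissimilarity matrix
    labels: np.ndarray    # 0..k-1 per sample
    metric: str = "precomputed"


# ---------------------------------------------------------------------------
# PAM
# ---------------------------------------------------------------------------

def pam_cluster(D: np.ndarray, k: int, max_swap_iter: int = 200) -> ClusteringResult:
    """PAM with greedy BUILD initialization and full SWAP phase.

    Minimizes total dissimilarity of samples to their nearest medoid.
    Deterministic: all ties break toward the lowest index.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if not (2 <= k < n):
        raise ClusteringError(f"need 2 <= k < n; got k={k}, n={n}")

    # BUILD: first medoid minimizes total distance, then greedy gain
    medoids = [int(np.argmin(D.sum(axis=1)))]
    dn = D[medoids[0]].copy()  # distance to nearest medoid
    while len(medoids) < k:
        gains = np.maximum(dn[None, :] - D, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        new = int(np.argmax(gains))
        medoids.append(new)
        dn = np.minimum(dn, D[new])

    def _assign(medoids):
        Dm = D[medoids]                   # k x n
        order = np.argsort(Dm, axis=0, kind="stable")
        nearest = order[0]                # medoid slot per sample
        # under all-tie degeneracy every sample lands in slot 0; medoids
        # still anchor their own clusters so none is empty
        nearest[medoids] = np.arange(len(medoids))
        dn = Dm[nearest, np.arange(n)]
        ds = Dm[order[1], np.arange(n)]   # second-nearest distance
        return nearest, dn, ds

    medoids = np.array(sorted(medoids))
    nearest, dn, ds = _assign(medoids)

    # SWAP: evaluate all (candidate, medoid) exchanges, vectorized per slot
    for _ in range(max_swap_iter):
        delta = np.empty((n, k))
        for i in range(k):
            in_i = nearest == i
            t1 = (np.minimum(D[:, in_i], ds[in_i][None, :]) - dn[in_i][None, :]).sum(axis=1)
            t2 = np.minimum(D[:, ~in_i] - dn[~in_i][None, :], 0.0).sum(axis=1)
            delta[:, i] = t1 + t2
        delta[medoids, :] = np.inf
        best = np.unravel_index(int(np.argmin(delta)), delta.shape)
        if delta[best] >= -1e-12:
            break
        x, i = int(best[0]), int(best[1])
        medoids = medoids.copy()
        medoids[i] = x
        medoids = np.array(sorted(medoids))
        nearest, dn, ds = _assign(medoids)

    labels = nearest
    return ClusteringResult(k=k, medoids=medoids, labels=labels)


def classify_to_medoids(D_to_medoids: np.ndarray) -> np.ndarray:
    """Assign each row to its nearest medoid column (ties: lowest index)."""
    return np.argmin(np.asarray(D_to_medoids, dtype=float), axis=1)


# ---------------------------------------------------------------------------
# Prediction strength
# ---------------------------------------------------------------------------

def _min_coclassification(val_labels: np.ndarray, assigned: np.ndarray, k: int) -> float:
    """Minimum over validation clusters of the same-assignment pair fraction.

    Validation clusters with fewer than two members have no pairs and
    contribute 1 (they cannot contradict the training clustering).
    """
    worst = 1.0
    for l in range(k):
        members = assigned[val_labels == l]
        n_l = len(members)
        if n_l < 2:
            continue
        counts = np.bincount(members)
        frac = float((counts * (counts - 1)).sum()) / (n_l * (n_l - 1))
        worst = min(worst, frac)
    return worst


@dataclass
class ClusterEvaluation:
    """Average prediction strength per k, with optional quality indices."""

    ps: dict[int, float]
    per_iteration: dict[int, list[float]] = field(default_factory=dict)
    indices: pd.DataFrame | None = None

    def select_k(self) -> int:
        """k >= 2 maximizing average prediction strength (ties: smallest k)."""
        ks = [k for k in sorted(self.ps) if k >= 2]
        return max(ks, key=lambda k: (self.ps[k], -k))


def prediction_strength(
    data: FeatureTable | np.ndarray,
    k_range: list[int] | range = range(2, 7),
    n_iter: int = 20,
    train_frac: float = 0.5,
    seed: int = 0,
    metric: str = "braycurtis",
) -> ClusterEvaluation:
    """Average prediction strength over random train/validation splits.

    In each of ``n_iter`` iterations samples are split at random; train and
    validation halves are clustered separately by PAM; validation samples
    are classified to the nearest training medoid; ps(k) is the minimum over
    validation clusters of the fraction of intra-cluster pairs that land in
    the same training cluster.  ps(1) is 1 by convention.
    """
    D = data if isinstance(data, np.ndarray) else dissimilarity(data, metric)
    n = D.shape[0]
    k_range = list(k_range)
    if n < 2 * max(k_range):
        raise ClusteringError(f"need n >= 2*k_max ({2 * max(k_range)}); got n={n}")
    rng = np.random.default_rng(seed)
    per_iter: dict[int, list[float]] = {k: [] for k in k_range}
    for _ in range(n_iter):
        perm = rng.permutation(n)
        n_train = int(round(train_frac * n))
        train, val = perm[:n_train], perm[n_train:]
        for k in k_range:
            tr = pam_cluster(D[np.ix_(train, train)], k)
            vl = pam_cluster(D[np.ix_(val, val)], k)
            assigned = classify_to_medoids(D[np.ix_(val, train[tr.medoids])])
            per_iter[k].append(_min_coclassification(vl.labels, assigned, k))
    ps = {k: float(np.mean(v)) for k, v in per_iter.items()}
    ps.setdefault(1, 1.0)  # a single cluster always "reproduces"
    return ClusterEvaluation(ps=ps, per_iteration=per_iter)


def generalized_prediction_strength(
    tables: dict[str, FeatureTable],
    k: int,
    metric: str = "braycurtis",
) -> pd.DataFrame:
    """Cross-study clustering agreement for a given k.

    Each study is clustered separately; validation-study samples are
    classified to the training study's medoids, and scored as in prediction
    strength.  Returns a study-by-study frame (training rows, validation
    columns; diagonal NaN) with a per-training-study average column.
    """
    studies = sorted(tables)
    if len(studies) < 2:
        raise ClusteringError("need at least 2 studies")
    feats = tables[studies[0]].feature_ids
    for s in studies[1:]:
        if tables[s].feature_ids != feats:
            raise ClusteringError("studies must share an identical feature space")
    stacked = np.vstack([tables[s].values for s in studies])
    sizes = [tables[s].shape[0] for s in studies]
    offs = np.concatenate([[0], np.cumsum(sizes)])
    D = dissimilarity(stacked, metric)

    idx = {s: np.arange(offs[i], offs[i + 1]) for i, s in enumerate(studies)}
    fits = {s: pam_cluster(D[np.ix_(idx[s], idx[s])], k) for s in studies}

    gps = pd.DataFrame(np.nan, index=studies, columns=studies)
    for train in studies:
        medoid_rows = idx[train][fits[train].medoids]
        for val in studies:
            if val == train:
                continue
            assigned = classify_to_medoids(D[np.ix_(idx[val], medoid_rows)])
            gps.loc[train, val] = _min_coclassification(fits[val].labels, assigned, k)
    gps["average"] = gps[studies].mean(axis=1)
    return gps


# ---------------------------------------------------------------------------
# Quality indices and the evaluation grid
# ---------------------------------------------------------------------------

def cluster_strength_indices(
    D: np.ndarray,
    labels: np.ndarray,
    data: np.ndarray | None = None,
) -> tuple[float | None, float]:
    """(Calinski-Harabasz, average silhouette width) for a labelling.

    Silhouette uses the dissimilarity matrix; CH needs the feature-space
    data and is None when it is not supplied.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ClusteringError("cluster indices undefined for a single cluster")
    sil = float(silhouette_score(D, labels, metric="precomputed"))
    ch = float(calinski_harabasz_score(data, labels)) if data is not None else None
    return ch, sil


def evaluate_k_range(
    tables: dict[str, FeatureTable],
    k_range: list[int] | range = range(2, 7),
    metrics: tuple[str, ...] = ("braycurtis",),
    n_iter: int = 20,
    seed: int = 0,
    cross_study: bool = True,
) -> pd.DataFrame:
    """Within-study (and optionally cross-study) clustering evaluation grid.

    Rows: study x dissimilarity x k, with average prediction strength,
    Calinski-Harabasz and average silhouette; plus, when more than one study
    is given, average generalized prediction strength per training study.
    """
    k_range = list(k_range)
    rows = []
    for metric in metrics:
        for study, table in sorted(tables.items()):
            D = dissimilarity(table, metric)
            ev = prediction_strength(D, k_range, n_iter=n_iter, seed=seed)
            for k in k_range:
                fit = pam_cluster(D, k)
                ch, sil = cluster_strength_indices(D, fit.labels, table.values)
                rows.append({
                    "study": study, "metric": metric, "k": k,
                    "prediction_strength": ev.ps[k],
                    "calinski_harabasz": ch, "silhouette": sil,
                })
        if cross_study and len(tables) > 1:
            for k in k_range:
                gps = generalized_prediction_strength(tables, k, metric)
                for study in gps.index:
                    rows.append({
                        "study": study, "metric": metric, "k": k,
                        "generalized_prediction_strength": float(gps.loc[study, "average"]),
                    })
    return pd.DataFrame(rows)
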