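"""Omnibus PERMANOVA testing and simulation scoring metrics.

PERMANOVA partitions the (Gower-centered) squared dissimilarity matrix by a
single variable tested marginally; R^2 is the between-group share of the
total sum of squares and the p-value comes from label permutations —
optionally restricted to within-block shuffles (per-sample variables under
repeated measures) or block-level shuffles (per-subject variables).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class EvaluationError(ValueError):
    pass


@dataclass
class PermanovaResult:
    variable: str
    r2: float
    pseudo_f: float
    p: float
    n_permutations: int
    scheme: str = "free"


def _r2_categorical(d2: np.ndarray, ss_total: float, codes: np.ndarray) -> float:
    ss_within = 0.0
    for g in np.unique(codes):
        idx = np.flatnonzero(codes == g)
        if len(idx) < 2:
            continue
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub.sum() / (2.0 * len(idx))
    return (ss_total - ss_within) / ss_total


def _r2_continuous(gower: np.ndarray, ss_total: float, x: np.ndarray) -> float:
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom <= 0:
        raise EvaluationError("variable is constant")
    return float(xc @ gower @ xc) / (denom * ss_total)


def permanova_r2(
    D: np.ndarray,
    variable: np.ndarray | pd.Series,
    n_perm: int = 2000,
    blocks: np.ndarray | pd.Series | None = None,
    scheme: str = "free",
    seed: int = 0,
    subset: np.ndarray | None = None,
) -> PermanovaResult:
    """Marginal PERMANOVA of one variable on a dissimilarity matrix.

    ``subset`` (boolean mask) restricts the test to a sample subset before
    anything is computed, implementing "conditional on" semantics.  With
    ``n_perm=0`` only R^2 and pseudo-F are returned (p is NaN); R^2 itself
    involves no permutation.  Permutation schemes: ``free``,
    ``within-block`` (shuffle values inside each block), ``block-level``
    (shuffle whole blocks of a block-constant variable).
    """
    D = np.asarray(D, dtype=float)
    var = pd.Series(np.asarray(variable, dtype=object)).reset_index(drop=True)
    name = getattr(variable, "name", None) or "variable"
    if subset is not None:
        subset = np.asarray(subset, dtype=bool)
        D = D[np.ix_(subset, subset)]
        var = var[subset].reset_index(drop=True)
        if blocks is not None:
            blocks = np.asarray(blocks, dtype=object)[subset]
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T, atol=1e-10) or np.abs(np.diag(D)).max() > 1e-10:
        raise EvaluationError("D must be square symmetric with a zero diagonal")

    # strings are always categorical: a label like "3" is a level, not a value
    arr = variable.to_numpy() if isinstance(variable, pd.Series) else np.asarray(variable)
    numeric = pd.api.types.is_numeric_dtype(arr.dtype) and arr.dtype != bool
    d2 = D**2
    ss_total = d2.sum() / (2.0 * n)

    if numeric:
        x = pd.to_numeric(var).to_numpy(dtype=float)
        if np.ptp(x) == 0:
            raise EvaluationError("variable is constant")
        J = np.eye(n) - np.ones((n, n)) / n
        gower = -0.5 * J @ d2 @ J
        stat = lambda v: _r2_continuous(gower, ss_total, v)
        values: np.ndarray = x
        df_b = 1
    else:
        codes = pd.factorize(var.astype(str))[0]
        if len(np.unique(codes)) < 2:
            raise EvaluationError("variable is constant")
        stat = lambda v: _r2_categorical(d2, ss_total, v)
        values = codes
        df_b = len(np.unique(codes)) - 1

    r2 = stat(values)
    df_w = n - df_b - 1
    if df_w <= 0:
        pseudo_f = np.nan
    elif r2 >= 1.0:
        pseudo_f = np.inf
    else:
        pseudo_f = (r2 / df_b) / ((1 - r2) / df_w)

    if n_perm <= 0:
        return PermanovaResult(name, float(r2), float(pseudo_f), np.nan, 0, scheme)

    rng = np.random.default_rng(seed)
    perm_fn = _make_permuter(values, blocks, scheme, rng)
    count = 0
    for _ in range(n_perm):
        if stat(perm_fn()) >= r2 - 1e-15:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return PermanovaResult(name, float(r2), float(pseudo_f), float(p), n_perm, scheme)


def _make_permuter(values: np.ndarray, blocks, scheme: str, rng: np.random.Generator):
    n = len(values)
    if scheme == "free" or blocks is None:
        return lambda: values[rng.permutation(n)]
    blocks = pd.Series(np.asarray(blocks, dtype=object)).astype(str).to_numpy()
    uniq = pd.unique(blocks)
    idx_of = {b: np.flatnonzero(blocks == b) for b in uniq}
    if scheme == "within-block":
        def permute() -> np.ndarray:
            out = values.copy()
            for b in uniq:
                idx = idx_of[b]
                out[idx] = values[idx[rng.permutation(len(idx))]]
            return out
        return permute
    if scheme == "block-level":
        block_vals = {}
        for b in uniq:
            v = values[idx_of[b]]
            if len(np.unique(v)) > 1:
                raise EvaluationError(
                    "block-level permutation requires the variable constant within blocks"
                )
            block_vals[b] = v[0]
        vals_arr = np.array([block_vals[b] for b in uniq])

        def permute() -> np.ndarray:
            shuffled = vals_arr[rng.permutation(len(uniq))]
            out = np.empty_like(values)
            for b, v in zip(uniq, shuffled):
                out[idx_of[b]] = v
            return out
        return permute
    raise EvaluationError(f"unknown permutation scheme {scheme!r}")


def false_positive_rate(pvals: np.ndarray | list[float], alpha: float = 0.05) -> float:
    """Fraction of nominal p-values below alpha."""
    p = np.asarray(pvals, dtype=float)
    p = p[np.isfinite(p)]
    if len(p) == 0:
        raise EvaluationError("no finite p-values")
    return float(np.mean(p < alpha))


def cluster_selection_success(true_k: int, selected_ks: list[int] | np.ndarray) -> float:
    """Fraction of replicates selecting the true number of clusters."""
    selected = np.asarray(selected_ks)
    return float(np.mean(selected == true_k))


def gradient_recovery(truth: np.ndarray, score: np.ndarray) -> dict[str, float]:
    """Sign-invariant correlation between a recovered score and the truth."""
    truth = np.asarray(truth, dtype=float)
    score = np.asarray(score, dtype=float)
    if np.std(score) == 0 or np.std(truth) == 0:
        return {"pearson_abs": 0.0, "spearman_abs": 0.0}
    return {
        "pearson_abs": float(abs(stats.pearsonr(truth, score)[0])),
        "spearman_abs": float(abs(stats.spearmanr(truth, score)[0])),
    }
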