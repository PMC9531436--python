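"""Zero-inflated, covariate-aware empirical-Bayes batch correction.

Non-zero counts of feature ``p`` in batch ``i`` are modelled as
``Y = exp{ beta_p' X + sigma_p (gamma_ip + delta_ip eps) } * I`` where ``I``
is the zero indicator, ``gamma_ip``/``delta_ip`` are batch location/scale
effects and ``eps`` is standard normal.  Batch parameters are shrunken with
ComBat's parametric empirical-Bayes priors (normal for location,
inverse-gamma for squared scale) and removed on the log scale of the
non-zero entries only: zeros are never altered, and each sample row is
re-scaled afterwards so its total abundance is unchanged.

The correction is intentionally conservative — it adjusts location/scale
batch effects it can confidently estimate and leaves presence/absence
patterns and poorly-observed batch-feature pairs untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mmuphin.data_model import FeatureTable, FeatureTableError, SampleMetadata

SIGMA_FLOOR = 1e-8
DELTA_FLOOR = 1e-8


class BatchCorrectionError(ValueError):
    pass


def _covariate_design(meta: SampleMetadata, covariate_names: list[str]) -> tuple[np.ndarray, list[str]]:
    """Reference-level dummy coding for categoricals, identity for numerics."""
    cols: list[np.ndarray] = []
    names: list[str] = []
    for name in covariate_names:
        if name not in meta.data.columns:
            raise KeyError(f"covariate {name!r} not in metadata")
        s = meta.data[name]
        if pd.api.types.is_numeric_dtype(s):
            cols.append(s.to_numpy(dtype=float))
            names.append(name)
        else:
            levels = sorted(s.astype(str).unique())
            for lev in levels[1:]:  # first sorted level is the reference
                cols.append((s.astype(str) == lev).to_numpy(dtype=float))
                names.append(f"{name}[{lev}]")
    if cols:
        return np.column_stack(cols), names
    return np.empty((len(meta.data), 0)), names


def _check_full_rank(design: np.ndarray, names: list[str]) -> None:
    """Error naming columns that are linearly dependent on earlier ones."""
    if design.shape[1] == 0:
        return
    rank = np.linalg.matrix_rank(design)
    if rank == design.shape[1]:
        return
    bad = []
    for j in range(1, design.shape[1]):
        if np.linalg.matrix_rank(design[:, : j + 1]) == np.linalg.matrix_rank(design[:, :j]):
            bad.append(names[j])
    raise BatchCorrectionError(
        f"design is rank deficient; collinear columns (batch confounding?): {bad}"
    )


@dataclass
class BatchCorrectionModel:
    """Fitted standardization and shrunken batch parameters.

    ``stand_mean`` is the batch-free fitted log mean per sample/feature
    (intercept-equivalent ``alpha_p`` plus covariate terms), ``sigma`` the
    per-feature pooled residual SD, ``gamma_star``/``delta_star`` the
    shrunken per-batch location/scale.  Batch-feature pairs with too few
    non-zero observations carry ``gamma_star=0, delta_star=1`` (identity).
    """

    batch_levels: list[str]
    feature_ids: list[str]
    batch_of_sample: np.ndarray  # integer batch index per sample
    stand_mean: np.ndarray       # samples x features
    sigma: np.ndarray            # features
    gamma_hat: np.ndarray        # batches x features (NaN where inestimable)
    delta_hat: np.ndarray        # batches x features (NaN where inestimable)
    gamma_star: np.ndarray       # batches x features
    delta_star: np.ndarray       # batches x features
    n_nonzero: np.ndarray        # batches x features
    correctable: np.ndarray      # batches x features, bool
    priors: dict = field(default_factory=dict)


def fit_standardization(
    table: FeatureTable,
    meta: SampleMetadata,
    covariate_names: list[str] | None = None,
    min_nonzero: int = 2,
) -> tuple[BatchCorrectionModel, np.ndarray]:
    """Per-feature regression of log non-zero counts on covariates + batch.

    Batch enters with a batch-size-weighted sum-to-zero convention (ComBat):
    the per-feature grand mean ``alpha_p`` is the non-zero-count-weighted
    average of batch-level fits, so the returned ``stand_mean`` is batch
    free.  Returns the model (with frequentist ``gamma_hat``/``delta_hat``
    and standardized residuals cached) and the zero mask.
    """
    covariate_names = covariate_names or []
    meta = meta.aligned_to(table)
    batch = meta.batch
    levels = sorted(batch.unique())
    if len(levels) < 2:
        raise BatchCorrectionError("need at least 2 batches to correct")
    counts = batch.value_counts()
    small = [lev for lev in levels if counts[lev] < 2]
    if small:
        raise BatchCorrectionError(f"batches with fewer than 2 samples: {small}")

    batch_idx = np.array([levels.index(b) for b in batch], dtype=int)
    n_samples, n_features = table.shape
    n_batches = len(levels)

    cov, cov_names = _covariate_design(meta, covariate_names)
    onehot = np.zeros((n_samples, n_batches))
    onehot[np.arange(n_samples), batch_idx] = 1.0
    design = np.column_stack([onehot, cov])
    _check_full_rank(design, [f"batch[{l}]" for l in levels] + cov_names)

    values = table.values
    mask = values > 0

    stand_mean = np.zeros((n_samples, n_features))
    sigma = np.ones(n_features)
    gamma_hat = np.full((n_batches, n_features), np.nan)
    delta_hat = np.full((n_batches, n_features), np.nan)
    n_nonzero = np.zeros((n_batches, n_features), dtype=int)
    correctable = np.zeros((n_batches, n_features), dtype=bool)
    zmat = np.full((n_samples, n_features), np.nan)  # standardized residuals

    logv = np.full_like(values, np.nan)
    np.log(values, out=logv, where=mask)

    for p in range(n_features):
        rows = mask[:, p]
        for i in range(n_batches):
            n_nonzero[i, p] = int(np.sum(rows & (batch_idx == i)))
        if rows.sum() < 2:
            continue  # uncorrectable feature: identity treatment
        y = logv[rows, p]
        D = design[rows]
        coef, *_ = np.linalg.lstsq(D, y, rcond=None)
        g = coef[:n_batches]
        c = coef[n_batches:]
        w = n_nonzero[:, p].astype(float)
        alpha = float(np.dot(w, g) / w.sum())
        sm = alpha + cov @ c if cov.shape[1] else np.full(n_samples, alpha)
        resid = y - D @ coef
        s = float(np.sqrt(np.mean(resid**2)))
        s = max(s, SIGMA_FLOOR)
        stand_mean[:, p] = sm
        sigma[p] = s
        z = (logv[rows, p] - sm[rows]) / s
        zmat[rows, p] = z
        for i in range(n_batches):
            sel = rows & (batch_idx == i)
            if n_nonzero[i, p] >= min_nonzero:
                zi = zmat[sel, p]
                gamma_hat[i, p] = float(np.mean(zi))
                delta_hat[i, p] = max(float(np.std(zi, ddof=1)), DELTA_FLOOR)
                correctable[i, p] = True

    model = BatchCorrectionModel(
        batch_levels=levels,
        feature_ids=table.feature_ids,
        batch_of_sample=batch_idx,
        stand_mean=stand_mean,
        sigma=sigma,
        gamma_hat=gamma_hat,
        delta_hat=delta_hat,
        gamma_star=np.zeros((n_batches, n_features)),
        delta_star=np.ones((n_batches, n_features)),
        n_nonzero=n_nonzero,
        correctable=correctable,
    )
    model.priors["zmat"] = zmat
    return model, mask


def _postmean(g_hat: np.ndarray, g_bar: float, n: np.ndarray, d2_star: np.ndarray, tau2: float) -> np.ndarray:
    return (tau2 * n * g_hat + d2_star * g_bar) / (tau2 * n + d2_star)


def eb_shrink(model: BatchCorrectionModel, shrink: bool = True, tol: float = 1e-4, max_iter: int = 500) -> BatchCorrectionModel:
    """ComBat parametric empirical-Bayes shrinkage of batch parameters.

    Per batch, a normal prior on location (moments across features) and an
    inverse-gamma prior on squared scale (method of moments), solved by the
    standard iterative conditional updates of the posterior means.
    """
    zmat = model.priors["zmat"]
    n_batches, n_features = model.gamma_hat.shape
    model.gamma_star = np.zeros_like(model.gamma_hat)
    model.delta_star = np.ones_like(model.delta_hat)

    for i in range(n_batches):
        est = model.correctable[i]
        g_hat = model.gamma_hat[i, est]
        d_hat2 = model.delta_hat[i, est] ** 2
        if not shrink or est.sum() < 3:
            if shrink and 0 < est.sum() < 3:
                warnings.warn(
                    f"batch {model.batch_levels[i]!r}: fewer than 3 estimable features; "
                    "shrinkage skipped (frequentist estimates used)"
                )
            model.gamma_star[i, est] = g_hat
            model.delta_star[i, est] = np.sqrt(d_hat2)
            continue

        g_bar = float(np.mean(g_hat))
        tau2 = float(np.var(g_hat, ddof=1))
        V = float(np.mean(d_hat2))
        S2 = float(np.var(d_hat2, ddof=1))
        rows = (model.batch_of_sample == i)
        # per-feature sum of squared deviations uses this batch's residuals
        zb = zmat[rows][:, est]
        n = model.n_nonzero[i, est].astype(float)

        if S2 < 1e-12 or tau2 < 1e-12:
            # degenerate spread across features: shrinkage is a no-op
            g_star = g_hat if tau2 >= 1e-12 else np.full_like(g_hat, g_bar)
            d2_star = d_hat2
        else:
            lam = (V**2 + 2 * S2) / S2        # inverse-gamma shape
            theta = (V**3 + V * S2) / S2      # inverse-gamma rate
            g_star = g_hat.copy()
            d2_star = d_hat2.copy()
            for _ in range(max_iter):
                g_new = _postmean(g_hat, g_bar, n, d2_star, tau2)
                ssq = np.nansum((zb - g_new[None, :]) ** 2, axis=0)
                d2_new = (theta + 0.5 * ssq) / (n / 2.0 + lam - 1.0)
                change = max(np.max(np.abs(g_new - g_star)), np.max(np.abs(d2_new - d2_star)))
                g_star, d2_star = g_new, d2_new
                if change < tol:
                    break
            model.priors[f"batch_{model.batch_levels[i]}"] = {
                "gamma_bar": g_bar, "tau2": tau2, "a_prior": lam, "b_prior": theta,
            }
        model.gamma_star[i, est] = g_star
        model.delta_star[i, est] = np.sqrt(np.maximum(d2_star, DELTA_FLOOR**2))
    return model


def apply_correction(table: FeatureTable, model: BatchCorrectionModel, mask: np.ndarray) -> FeatureTable:
    """Remove shrunken batch location/scale effects from non-zero entries.

    Corrected non-zero value:
    ``exp{ (log Y - stand_mean - gamma*_i sigma) / delta*_i + stand_mean }``.
    Zeros stay zero and each sample row is rescaled to its pre-correction
    total so read depth is unchanged.
    """
    if model.feature_ids != table.feature_ids:
        raise BatchCorrectionError("model and table feature sets differ")
    values = table.values
    if not np.array_equal(mask, values > 0):
        raise BatchCorrectionError("zero mask does not match the table")
    bidx = model.batch_of_sample
    gam = model.gamma_star[bidx]    # samples x features
    dlt = model.delta_star[bidx]
    out = np.zeros_like(values)
    logv = np.log(values, out=np.full_like(values, np.nan), where=mask)
    adj = (logv - model.stand_mean - gam * model.sigma[None, :]) / dlt + model.stand_mean
    out[mask] = np.exp(adj[mask])

    totals_before = values.sum(axis=1)
    totals_after = out.sum(axis=1)
    scale = np.divide(totals_before, totals_after, out=np.ones_like(totals_before), where=totals_after > 0)
    out *= scale[:, None]
    return table.with_values(out)


def correct(
    table: FeatureTable,
    meta: SampleMetadata,
    covariate_names: list[str] | None = None,
    shrink: bool = True,
    min_nonzero: int = 2,
) -> FeatureTable:
    """Full correction pipeline: standardize, shrink, apply.

    Deterministic given inputs.  Accepts counts or relative abundances; for
    relative input, per-sample re-normalization re-closes the composition.
    """
    model, mask = fit_standardization(table, meta, covariate_names, min_nonzero=min_nonzero)
    model = eb_shrink(model, shrink=shrink)
    return apply_correction(table, model, mask)
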