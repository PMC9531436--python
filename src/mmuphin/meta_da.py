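"""Meta-analytic differential abundance testing.

Within each study, arcsin-sqrt-transformed relative abundances are regressed
on an exposure plus covariates (ordinary least squares, or a random-intercept
linear mixed model for repeated-measures designs).  Per-study exposure
effects ``beta_ip`` with sampling variances are then pooled per feature
under the model ``beta_ip = beta_p + eps_ip + e_ip`` by fixed- or
random-effects meta-analysis; the between-study variance ``tau^2`` is
estimated by restricted maximum likelihood.  Moderator (meta-regression)
models test whether effects differ systematically between strata, and
ordered contrast models compare severity levels.  P-values are adjusted by
Benjamini-Hochberg FDR across features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar
from statsmodels.stats.multitest import multipletests

from mmuphin.data_model import (
    FeatureTable,
    SampleMetadata,
    arcsin_sqrt_transform,
    tss_normalize,
)


class MetaDAError(ValueError):
    pass


@dataclass
class StudyEffect:
    """Exposure effect of one feature in one study, on the arcsin-sqrt scale."""

    study: str
    feature: str
    beta: float
    se: float
    n_used: int
    model: str = "linear"  # "linear" | "random-intercept"


@dataclass
class PooledEffect:
    """Meta-analysis pooled effect for one feature."""

    feature: str
    beta: float
    se: float
    tau2: float
    z: float
    p: float
    k: int
    weights: np.ndarray
    q: float = np.nan


# ---------------------------------------------------------------------------
# Per-study model
# ---------------------------------------------------------------------------

def _exposure_column(series: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Numeric exposure vector and a validity mask (missing rows dropped)."""
    if pd.api.types.is_numeric_dtype(series):
        x = series.to_numpy(dtype=float)
        return x, np.isfinite(x)
    s = series.astype(str)
    valid = (s != "missing").to_numpy()
    levels = sorted(s[valid].unique())
    if len(levels) == 1:
        return np.zeros(len(s)), valid  # constant; caller handles
    if len(levels) > 2:
        raise MetaDAError(
            f"exposure has {len(levels)} levels; use contrast_models for ordinal exposures"
        )
    x = (s == levels[1]).to_numpy(dtype=float)
    return x, valid


def _design(meta: SampleMetadata, exposure: str, covariates: list[str]) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Design matrix [intercept, exposure, covariates...], plus validity mask."""
    x, valid = _exposure_column(meta.data[exposure])
    cols = [np.ones(len(x)), x]
    names = ["intercept", exposure]
    for name in covariates:
        s = meta.data[name]
        if pd.api.types.is_numeric_dtype(s):
            v = s.to_numpy(dtype=float)
            valid &= np.isfinite(v)
            cols.append(np.where(np.isfinite(v), v, 0.0))
            names.append(name)
        else:
            ss = s.astype(str)
            valid &= (ss != "missing").to_numpy()
            levels = [l for l in sorted(ss.unique()) if l != "missing"]
            for lev in levels[1:]:
                cols.append((ss == lev).to_numpy(dtype=float))
                names.append(f"{name}[{lev}]")
    return np.column_stack(cols), valid, names


def fit_study_model(
    table: FeatureTable,
    meta: SampleMetadata,
    exposure: str,
    covariates: list[str] | None = None,
    random_group: str | None = None,
    study_id: str = "study",
) -> list[StudyEffect]:
    """Per-feature exposure effects within a single study.

    Relative abundances are arcsin-sqrt transformed internally.  Plain OLS
    is used unless ``random_group`` names a subject column with repeated
    measures, in which case a random-intercept mixed model (REML) is fitted
    per feature.  Features that are entirely absent in the study, or an
    exposure that does not vary, yield no effect (the feature is "absent"
    from this study's contribution rather than a zero).
    """
    covariates = covariates or []
    meta = meta.aligned_to(table)
    rel = table if table.is_relative else tss_normalize(table)
    Y = arcsin_sqrt_transform(rel)

    X, valid, names = _design(meta, exposure, covariates)
    X, Y = X[valid], Y[valid]
    if X.shape[0] < X.shape[1] + 1 or np.ptp(X[:, 1]) == 0:
        return []  # exposure constant (or no data): every feature absent
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise MetaDAError(f"singular design in study {study_id!r}: columns {names}")

    present = table.values.sum(axis=0) > 0
    feature_ids = table.feature_ids

    groups = None
    if random_group is not None and random_group in meta.data.columns:
        g = meta.data[random_group].astype(str).to_numpy()[valid]
        if pd.Series(g).value_counts().max() >= 2:
            groups = g

    effects: list[StudyEffect] = []
    if groups is None:
        XtX_inv = np.linalg.inv(X.T @ X)
        H = XtX_inv @ X.T
        B = H @ Y                      # coefficients, q x features
        resid = Y - X @ B
        dof = X.shape[0] - X.shape[1]
        sigma2 = (resid**2).sum(axis=0) / dof
        se = np.sqrt(sigma2 * XtX_inv[1, 1])
        for p_idx in np.flatnonzero(present):
            if not np.isfinite(se[p_idx]) or se[p_idx] <= 0:
                continue
            effects.append(
                StudyEffect(study_id, feature_ids[p_idx], float(B[1, p_idx]),
                            float(se[p_idx]), X.shape[0], "linear")
            )
    else:
        import statsmodels.api as sm

        for p_idx in np.flatnonzero(present):
            y = Y[:, p_idx]
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = sm.MixedLM(y, X, groups=groups).fit(reml=True)
                beta, se_b = float(fit.params[1]), float(fit.bse[1])
            except Exception:
                continue
            if np.isfinite(beta) and np.isfinite(se_b) and se_b > 0:
                effects.append(
                    StudyEffect(study_id, feature_ids[p_idx], beta, se_b,
                                X.shape[0], "random-intercept")
                )
    return effects


# ---------------------------------------------------------------------------
# Pooling
# ---------------------------------------------------------------------------

def _reml_tau2(y: np.ndarray, v: np.ndarray, X: np.ndarray | None = None) -> float:
    """Between-study variance by restricted maximum likelihood.

    Maximizes the restricted log-likelihood over ``tau2 >= 0`` by bounded
    scalar optimization (profiling out the mean/meta-regression
    coefficients).  ``X`` defaults to an intercept-only design.
    """
    if X is None:
        X = np.ones((len(y), 1))
    if len(y) <= X.shape[1]:
        return 0.0

    def neg_restricted_ll(tau2: float) -> float:
        w = 1.0 / (v + tau2)
        XtWX = X.T @ (X * w[:, None])
        beta = np.linalg.solve(XtWX, X.T @ (w * y))
        r = y - X @ beta
        sign, logdet = np.linalg.slogdet(XtWX)
        return 0.5 * (np.sum(np.log(v + tau2)) + logdet + np.sum(w * r**2))

    upper = max(float(np.var(y, ddof=1)) * 10.0, float(np.max(v)) * 10.0, 1e-6)
    res = minimize_scalar(neg_restricted_ll, bounds=(0.0, upper), method="bounded",
                          options={"xatol": 1e-10})
    tau2 = float(res.x)
    if neg_restricted_ll(0.0) <= res.fun:
        tau2 = 0.0
    return max(tau2, 0.0)


def dersimonian_laird_tau2(y: np.ndarray, v: np.ndarray) -> float:
    """Method-of-moments between-study variance (DerSimonian-Laird)."""
    w = 1.0 / v
    mu = np.sum(w * y) / np.sum(w)
    Q = np.sum(w * (y - mu) ** 2)
    c = np.sum(w) - np.sum(w**2) / np.sum(w)
    if c <= 0:
        return 0.0
    return max((Q - (len(y) - 1)) / c, 0.0)


def pool_effects(effects: list[StudyEffect], method: str = "random") -> PooledEffect | None:
    """Inverse-variance pooling of one feature's per-study effects.

    ``method="fixed"`` sets ``tau2 = 0``; ``method="random"`` estimates
    ``tau2`` by REML.  Returns None when no study contributed an estimate.
    """
    if not effects:
        return None
    feature = effects[0].feature
    y = np.array([e.beta for e in effects])
    v = np.array([e.se**2 for e in effects])
    if method == "fixed" or len(y) == 1:
        tau2 = 0.0
    elif method == "random":
        tau2 = _reml_tau2(y, v)
    else:
        raise ValueError("method must be 'fixed' or 'random'")
    w = 1.0 / (v + tau2)
    weights = w / w.sum()
    beta = float(np.sum(w * y) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    z = beta / se
    p = float(2 * stats.norm.sf(abs(z)))
    return PooledEffect(feature, beta, se, float(tau2), float(z), p, len(y), weights)


def moderator_test(
    effects_by_stratum: dict[str, list[StudyEffect]],
    moderator: dict[str, int | bool],
) -> pd.DataFrame:
    """Random-effects meta-regression of stratum effects on a binary moderator.

    ``moderator`` maps stratum id -> 0/1.  Returns per-feature intercept
    ``beta0``, interaction ``beta1`` with its SE and p-value.
    """
    strata = sorted(effects_by_stratum)
    mod = {s: int(bool(moderator[s])) for s in strata}
    if len(set(mod.values())) < 2:
        raise MetaDAError("moderator is constant across strata")

    per_feature: dict[str, list[tuple[float, float, int]]] = {}
    for s in strata:
        for e in effects_by_stratum[s]:
            per_feature.setdefault(e.feature, []).append((e.beta, e.se**2, mod[s]))

    rows = []
    for feature, triples in sorted(per_feature.items()):
        y = np.array([t[0] for t in triples])
        v = np.array([t[1] for t in triples])
        m = np.array([t[2] for t in triples], dtype=float)
        if len(set(m)) < 2:
            continue
        X = np.column_stack([np.ones_like(m), m])
        tau2 = _reml_tau2(y, v, X) if len(y) > 2 else 0.0
        w = 1.0 / (v + tau2)
        XtWX_inv = np.linalg.inv(X.T @ (X * w[:, None]))
        beta = XtWX_inv @ (X.T @ (w * y))
        se1 = float(np.sqrt(XtWX_inv[1, 1]))
        z1 = beta[1] / se1
        rows.append({
            "feature": feature, "beta0": float(beta[0]), "beta1": float(beta[1]),
            "se1": se1, "p1": float(2 * stats.norm.sf(abs(z1))), "tau2": float(tau2),
            "k": len(y),
        })
    out = pd.DataFrame(rows)
    if not out.empty:
        out["q1"] = bh_adjust(out["p1"].to_numpy())
    return out


def bh_adjust(pvals: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment (NaNs propagate)."""
    p = np.asarray(pvals, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

@dataclass
class MetaDAResult:
    """Pooled per-feature results plus the per-study effects behind them."""

    results: pd.DataFrame
    study_effects: list[StudyEffect]

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.results[self.results["q"] < alpha]


def run_meta_da(
    table: FeatureTable,
    meta: SampleMetadata,
    exposure: str,
    covariates: list[str] | None = None,
    strata: str | None = None,
    method: str = "random",
    random_group: str | None = None,
) -> MetaDAResult:
    """Stratify by study (and optionally a stratum column), fit, pool, adjust.

    Studies come from the metadata's study column (the batch column when no
    study column is set); an optional ``strata`` column further subdivides
    them before per-stratum model fitting.
    """
    meta = meta.aligned_to(table)
    labels = meta.study.astype(str)
    if strata is not None:
        labels = labels + "::" + meta.data[strata].astype(str)

    all_effects: list[StudyEffect] = []
    for stratum in sorted(labels.unique()):
        keep = (labels == stratum).to_numpy()
        sub_table = FeatureTable(table.data.loc[keep], is_relative=table.is_relative)
        sub_meta = SampleMetadata(
            meta.data.loc[keep].copy(), batch_col=meta.batch_col,
            study_col=meta.study_col, subject_col=meta.subject_col,
        )
        all_effects.extend(
            fit_study_model(sub_table, sub_meta, exposure, covariates,
                            random_group=random_group, study_id=stratum)
        )

    by_feature: dict[str, list[StudyEffect]] = {}
    for e in all_effects:
        by_feature.setdefault(e.feature, []).append(e)

    rows = []
    for feature in table.feature_ids:
        pooled = pool_effects(by_feature.get(feature, []), method=method)
        if pooled is None:
            continue
        rows.append({
            "feature": feature, "beta": pooled.beta, "se": pooled.se,
            "tau2": pooled.tau2, "z": pooled.z, "p": pooled.p, "k": pooled.k,
        })
    results = pd.DataFrame(rows)
    if not results.empty:
        results["q"] = bh_adjust(results["p"].to_numpy())
    return MetaDAResult(results=results, study_effects=all_effects)


def contrast_models(
    table: FeatureTable,
    meta: SampleMetadata,
    exposure: str,
    levels: tuple[str, str, str],
    covariates: list[str] | None = None,
    method: str = "random",
    alpha: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Ordered three-level contrasts pooled across studies.

    For levels ``(L1, L2, L3)`` this returns pooled effects for L2-vs-L1 and
    L3-vs-L1 (each fitted on the corresponding two-level subset) and the
    incremental L3 effect ``beta2`` from the joint model with indicators
    I{L2 or L3} and I{L3}.  FDR for ``beta2`` is computed only across
    features significant (q < alpha) in either pairwise contrast.
    """
    L1, L2, L3 = levels
    meta = meta.aligned_to(table)
    lab = meta.data[exposure].astype(str)

    def subset(mask: np.ndarray) -> tuple[FeatureTable, SampleMetadata]:
        t = FeatureTable(table.data.loc[mask], is_relative=table.is_relative)
        m = SampleMetadata(meta.data.loc[mask].copy(), batch_col=meta.batch_col,
                           study_col=meta.study_col, subject_col=meta.subject_col)
        return t, m

    out: dict[str, pd.DataFrame] = {}
    for name, hi in (("L2_vs_L1", L2), ("L3_vs_L1", L3)):
        mask = lab.isin([L1, hi]).to_numpy()
        if mask.sum() == 0:
            out[name] = pd.DataFrame()
            continue
        t, m = subset(mask)
        m.data["_contrast"] = (m.data[exposure].astype(str) == hi).astype(float)
        res = run_meta_da(t, m, "_contrast", covariates, method=method)
        out[name] = res.results

    # joint model: beta1 I{L2 or L3} + beta2 I{L3}
    mask = lab.isin([L1, L2, L3]).to_numpy()
    t, m = subset(mask)
    m.data["_l23"] = m.data[exposure].astype(str).isin([L2, L3]).astype(float)
    m.data["_l3"] = (m.data[exposure].astype(str) == L3).astype(float)
    joint = run_meta_da(t, m, "_l3", covariates=(covariates or []) + ["_l23"], method=method)
    jres = joint.results.rename(columns={"beta": "beta2", "se": "se2", "p": "p2"})
    if "q" in jres.columns:
        jres = jres.drop(columns=["q"])

    flagged: set[str] = set()
    for name in ("L2_vs_L1", "L3_vs_L1"):
        df = out[name]
        if not df.empty:
            flagged |= set(df.loc[df["q"] < alpha, "feature"])
    if not jres.empty:
        in_pool = jres["feature"].isin(flagged).to_numpy()
        q2 = np.full(len(jres), np.nan)
        if in_pool.any():
            q2[in_pool] = bh_adjust(jres.loc[in_pool, "p2"].to_numpy())
        jres["q2"] = q2
    out["L3_incremental"] = jres
    return out
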