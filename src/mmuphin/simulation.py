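"""Zero-inflated log-normal community simulator with metadata spike-in.

Null abundances are drawn per feature as
``Y_ip ~ LogNormal(mu_p, sigma_p^2) * Bernoulli(pi_p)``.  Associations with
metadata are spiked in by the re-standardization formula

``Y~_ip = (Y_ip + phi * [ (X_i - mu_X) sigma_Y / sigma_X + mu_Y ]) / (1 + phi)``

which preserves the feature's pre-spike mean and (approximately) variance
while inducing a controlled association of strength ``phi`` with ``X``.
By default the formula is applied to a feature's non-zero entries (its
moments taken over those entries), so technical/biological absences are not
converted into presences by metadata alone; ``spike_zeros=True`` applies
the formula to the whole count vector instead.  Negative post-spike values
are truncated at zero (abundances are non-negative); the truncated count is
recorded in the truth record.

Categorical variables (batch, cluster labels) are spiked one binary level
indicator at a time.  Each level indicator perturbs half the variable's
feature budget (``pct_spiked * P / 2``), drawn as its own random target
subset; a binary variable's two level indicators are complementary and
collapse to a single indicator carrying the full budget.

Scenario builders assemble the four evaluation designs used to validate the
framework: batch + positive/negative control covariates, a study-confounded
null for false-positive-rate testing, planted discrete clusters, and a
planted continuous gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np
import pandas as pd

from mmuphin.data_model import FeatureTable, SampleMetadata

SIGMA_FLOOR = 1e-8
_DEFAULT_PARAMS_SEED = 20200721  # fixed: the packaged default null is one set


@dataclass
class NullModelParams:
    """Per-feature zero-inflated log-normal parameters."""

    mu: np.ndarray     # log-scale location
    sigma: np.ndarray  # log-scale SD, > 0
    pi: np.ndarray     # presence probability, (0, 1]

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        if (self.sigma <= 0).any():
            raise ValueError("sigma must be positive")
        if (self.pi < 0).any() or (self.pi > 1).any():
            raise ValueError("pi must lie in [0, 1]")

    @property
    def n_features(self) -> int:
        return len(self.mu)


def default_null_params(n_features: int) -> NullModelParams:
    """Packaged stool-like default null parameters.

    Log-abundance locations follow a log-normal species-abundance spread (a
    few dominant features, a long tail), presence probability increases with
    abundance (dominant taxa are near-core, rare taxa heavily zero-inflated),
    and locations are offset so a sample's expected total count is ~3e4.
    Deterministic for a given feature count.
    """
    rng = np.random.default_rng(_DEFAULT_PARAMS_SEED)
    a = np.clip(rng.normal(0.0, 1.5, n_features), -2.7, 2.7)
    sigma = rng.uniform(0.5, 2.0, n_features)
    pi = np.clip(1.0 / (1.0 + np.exp(-(0.5 * a - 1.4))), 0.02, 0.98)
    expected = pi * np.exp(a + sigma**2 / 2.0)
    offset = np.log(3e4) - np.log(expected.sum())
    return NullModelParams(mu=a + offset, sigma=sigma, pi=pi)


def fit_null_model(table: FeatureTable) -> NullModelParams:
    """Estimate (mu, sigma, pi) from a count table.

    ``pi`` is the non-zero fraction; ``mu``/``sigma`` the mean/SD of log
    counts over non-zero entries.  Features with fewer than two non-zero
    entries get the sigma floor.
    """
    values = table.values
    mask = values > 0
    n = values.shape[0]
    pi = mask.mean(axis=0)
    mu = np.zeros(values.shape[1])
    sigma = np.full(values.shape[1], SIGMA_FLOOR)
    for p in range(values.shape[1]):
        nz = values[mask[:, p], p]
        if len(nz) >= 1:
            logs = np.log(nz)
            mu[p] = logs.mean()
            if len(nz) >= 2:
                sigma[p] = max(float(np.std(logs, ddof=1)), SIGMA_FLOOR)
    return NullModelParams(mu=mu, sigma=sigma, pi=pi)


def sample_null(
    params: NullModelParams,
    n_samples: int,
    seed: int | np.random.Generator = 0,
) -> FeatureTable:
    """Independent zero-inflated log-normal draws, reproducible under seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    P = params.n_features
    logs = rng.normal(params.mu[None, :], params.sigma[None, :], size=(n_samples, P))
    present = rng.random((n_samples, P)) < params.pi[None, :]
    values = np.exp(logs) * present
    df = pd.DataFrame(
        values,
        index=[f"S{j:05d}" for j in range(n_samples)],
        columns=[f"F{p:04d}" for p in range(P)],
    )
    return FeatureTable(df, is_relative=False)


def spike_in(
    values: np.ndarray,
    x: np.ndarray,
    targets: np.ndarray,
    phi: float,
    spike_zeros: bool = False,
) -> tuple[np.ndarray, int]:
    """Apply the re-standardization spike-in to the target feature columns.

    Moments ``mu_Y``/``sigma_Y`` are the sample moments of each target
    column before this spike.  By default only non-zero entries are spiked
    (moments over those entries) and the zero pattern is preserved exactly:
    negative post-formula values are floored at the feature's smallest
    pre-spike positive value so spiking never creates absence.
    ``spike_zeros=True`` applies the formula to the full count vector
    instead, with negatives truncated to zero as written (spiking can then
    both create and destroy presence).  Returns the new matrix and the
    number of entries that fell below zero.
    """
    if phi < 0:
        raise ValueError("phi must be non-negative")
    x = np.asarray(x, dtype=float)
    sx = float(np.std(x, ddof=1))
    if sx <= 0:
        raise ValueError("spiked metadata variable is constant")
    if phi == 0:
        return values.copy(), 0
    out = values.copy()
    mx = float(np.mean(x))
    xs = (x - mx) / sx
    n_trunc = 0
    for p in np.atleast_1d(targets):
        col = out[:, p]
        rows = slice(None) if spike_zeros else col > 0
        sub = col[rows]
        if sub.size < 2:
            continue
        mu_y = float(np.mean(sub))
        sd_y = float(np.std(sub, ddof=1))
        new = (sub + phi * (xs[rows] * sd_y + mu_y)) / (1.0 + phi)
        n_trunc += int((new < 0).sum())
        floor = 0.0 if spike_zeros else float(sub.min())
        col[rows] = np.maximum(new, floor)
        out[:, p] = col
    return out, n_trunc


def _spike_categorical(
    values: np.ndarray,
    labels: np.ndarray,
    phi: float,
    pct_spiked: float,
    rng: np.random.Generator,
    spike_zeros: bool = False,
) -> tuple[np.ndarray, dict[str, np.ndarray], int]:
    """Spike level indicators, each carrying half the variable's budget.

    The variable's feature budget is ``round(pct_spiked * P)``.  Each level
    indicator perturbs half of it (an indicator contrasts two sample
    groups, its level against the rest); for a binary variable the two
    complementary indicators collapse into one carrying the full budget.
    """
    P = values.shape[1]
    n_total = max(int(round(pct_spiked * P)), 1) if pct_spiked > 0 else 0
    spiked: dict[str, np.ndarray] = {}
    n_trunc = 0
    if n_total == 0 or phi == 0:
        return values, spiked, 0
    levels = sorted(pd.unique(labels.astype(str)))
    if len(levels) < 2:
        return values, spiked, 0  # a single level carries no contrast
    if len(levels) == 2:
        indicator_levels = levels[1:]
        per_level = n_total
    else:
        indicator_levels = levels
        per_level = max(int(round(n_total / 2)), 1)
    for lev in indicator_levels:
        targets = np.sort(rng.choice(P, size=per_level, replace=False))
        ind = (labels.astype(str) == lev).astype(float)
        values, t = spike_in(values, ind, targets, phi, spike_zeros=spike_zeros)
        spiked[lev] = targets
        n_trunc += t
    return values, spiked, n_trunc


def _spike_numeric(
    values: np.ndarray,
    x: np.ndarray,
    phi: float,
    pct_spiked: float,
    rng: np.random.Generator,
    spike_zeros: bool = False,
) -> tuple[np.ndarray, np.ndarray, int]:
    P = values.shape[1]
    n_targets = max(int(round(pct_spiked * P)), 1) if pct_spiked > 0 else 0
    if n_targets == 0 or phi == 0:
        return values, np.array([], dtype=int), 0
    targets = np.sort(rng.choice(P, size=n_targets, replace=False))
    values, n_trunc = spike_in(values, x, targets, phi, spike_zeros=spike_zeros)
    return values, targets, n_trunc


@dataclass
class SimulationScenario:
    """Serializable description of one simulated evaluation design."""

    kind: str
    n_batches: int = 2
    samples_per_batch: int = 100
    n_features: int = 200
    pct_spiked: float = 0.10
    effect_batch: float = 10.0
    effect_binary: float = 10.0
    effect_continuous: float = 10.0
    effect_cluster: float = 10.0
    effect_gradient: float = 10.0
    imbalance: float = 0.8
    n_clusters: int = 3
    spike_zeros: bool = False
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimulationScenario":
        return cls(**d)


def make_scenario(
    scenario: SimulationScenario,
    params: NullModelParams | None = None,
) -> tuple[FeatureTable, SampleMetadata, dict[str, Any]]:
    """Assemble a simulated table, metadata, and ground-truth record.

    Kinds
    -----
    ``batch_covariate``
        batch + binary/continuous positive controls (spiked) + binary
        negative control (not spiked).
    ``confounded_null``
        batch-spiked null with a binary exposure unevenly distributed
        across batches (per-batch case fraction ``0.5 +/- imbalance/2``)
        but not associated with any feature.
    ``discrete_clusters``
        batch + a planted discrete cluster variable, both spiked.
    ``continuous_gradient``
        batch + a planted Uniform(-1, 1) gradient, both spiked.
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    if params is None:
        params = default_null_params(sc.n_features)
    if params.n_features != sc.n_features:
        raise ValueError("null parameter set does not match n_features")

    n = sc.n_batches * sc.samples_per_batch
    batch = np.repeat([f"B{i}" for i in range(sc.n_batches)], sc.samples_per_batch)
    table = sample_null(params, n, seed=rng)
    values = table.values
    truth: dict[str, Any] = {"scenario": sc.to_dict(), "n_truncated": 0}

    meta = pd.DataFrame({"batch": batch}, index=table.sample_ids)

    values, spiked_batch, t = _spike_categorical(values, batch, sc.effect_batch, sc.pct_spiked, rng, sc.spike_zeros)
    truth["spiked_batch"] = {k: v.tolist() for k, v in spiked_batch.items()}
    truth["n_truncated"] += t

    if sc.kind == "batch_covariate":
        pos_bin = rng.integers(0, 2, n)
        pos_cont = rng.normal(0.0, 1.0, n)
        neg_bin = rng.integers(0, 2, n)
        values, tg, t1 = _spike_numeric(values, pos_bin.astype(float), sc.effect_binary, sc.pct_spiked, rng, sc.spike_zeros)
        truth["spiked_pos_binary"] = tg.tolist()
        values, tg, t2 = _spike_numeric(values, pos_cont, sc.effect_continuous, sc.pct_spiked, rng, sc.spike_zeros)
        truth["spiked_pos_continuous"] = tg.tolist()
        truth["n_truncated"] += t1 + t2
        meta["pos_binary"] = pd.Series(pos_bin, index=meta.index).astype(str)
        meta["pos_continuous"] = pos_cont
        meta["neg_binary"] = pd.Series(neg_bin, index=meta.index).astype(str)
    elif sc.kind == "confounded_null":
        case_frac = np.empty(n)
        for i in range(sc.n_batches):
            rows = batch == f"B{i}"
            # alternate enrichment/depletion of cases across batches
            shift = sc.imbalance / 2.0 if i % 2 else -sc.imbalance / 2.0
            case_frac[rows] = np.clip(0.5 + shift, 0.0, 1.0)
        exposure = (rng.random(n) < case_frac).astype(int)
        meta["exposure"] = pd.Series(exposure, index=meta.index).astype(str)
        truth["exposure_null"] = True
    elif sc.kind == "discrete_clusters":
        if sc.n_clusters * 2 > n:
            raise ValueError(
                f"{sc.n_clusters} clusters cannot be populated by {n} samples"
            )
        clusters = rng.integers(0, sc.n_clusters, n)
        labels = np.array([f"C{c}" for c in clusters])
        values, spiked_cl, t = _spike_categorical(values, labels, sc.effect_cluster, sc.pct_spiked, rng, sc.spike_zeros)
        truth["spiked_cluster"] = {k: v.tolist() for k, v in spiked_cl.items()}
        truth["cluster_labels"] = labels.tolist()
        truth["n_clusters"] = sc.n_clusters
        truth["n_truncated"] += t
    elif sc.kind == "continuous_gradient":
        gradient = rng.uniform(-1.0, 1.0, n)
        values, tg, t = _spike_numeric(values, gradient, sc.effect_gradient, sc.pct_spiked, rng, sc.spike_zeros)
        truth["spiked_gradient"] = tg.tolist()
        truth["gradient"] = gradient.tolist()
        truth["n_truncated"] += t
    else:
        raise ValueError(f"unknown scenario kind {sc.kind!r}")

    out_table = table.with_values(values)
    out_meta = SampleMetadata(meta, batch_col="batch")
    return out_table, out_meta, truth
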