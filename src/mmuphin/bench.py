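"""End-to-end simulation benchmarks for every analysis component.

Each benchmark generates data from the zero-inflated log-normal simulator
under one of the evaluation designs, runs the corresponding analysis with
and (where relevant) without batch correction, and scores the result:
PERMANOVA R^2 for batch-effect reduction, false-positive rate for the
confounded-null meta-analysis, cluster-number recovery for discrete
structure, and gradient correlation for continuous structure.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from mmuphin.batch_correction import correct
from mmuphin.data_model import FeatureTable, SampleMetadata, bray_curtis, tss_normalize
from mmuphin.discrete import prediction_strength
from mmuphin.continuous import assign_scores, discover_gradients
from mmuphin.evaluation import (
    false_positive_rate,
    gradient_recovery,
    permanova_r2,
)
from mmuphin.meta_da import fit_study_model, run_meta_da
from mmuphin.simulation import SimulationScenario, make_scenario


def _child_seeds(seed: int, n: int) -> list[int]:
    """Derive n reproducible sub-seeds below 2**31 from one master seed."""
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def _bc(table: FeatureTable) -> np.ndarray:
    return bray_curtis(tss_normalize(table))


def permanova_anchor(
    seed: int = 0,
    n_replicates: int = 5,
    n_batches: int = 8,
    samples_per_batch: int = 500,
    n_features: int = 200,
    pct_spiked: float = 0.10,
    effect_batch: float = 10.0,
    effect_controls: float = 10.0,
) -> pd.DataFrame:
    """Batch and binary-exposure PERMANOVA R^2 on the anchor design.

    The design spikes batch (per level) and binary/continuous positive
    controls into random feature subsets; R^2 is computed marginally on
    Bray-Curtis dissimilarities of the relative abundances (no permutations
    are needed for R^2 itself).  Values are percentages.
    """
    rows = []
    for s in _child_seeds(seed, n_replicates):
        sc = SimulationScenario(
            kind="batch_covariate", n_batches=n_batches,
            samples_per_batch=samples_per_batch, n_features=n_features,
            pct_spiked=pct_spiked, effect_batch=effect_batch,
            effect_binary=effect_controls, effect_continuous=effect_controls,
            seed=s,
        )
        table, meta, _ = make_scenario(sc)
        D = _bc(table)
        r2_batch = permanova_r2(D, meta.batch, n_perm=0).r2
        r2_exposure = permanova_r2(D, meta.data["pos_binary"], n_perm=0).r2
        rows.append({"seed": s, "r2_batch_pct": 100 * r2_batch,
                     "r2_exposure_pct": 100 * r2_exposure})
    return pd.DataFrame(rows)


def fpr_benchmark(
    seed: int = 0,
    n_replicates: int = 20,
    n_batches: int = 2,
    samples_per_batch: int = 100,
    n_features: int = 200,
    pct_spiked: float = 0.10,
    effect_batch: float = 10.0,
    imbalance: float = 0.8,
) -> pd.DataFrame:
    """False-positive rates on study-confounded null data.

    Per replicate: (a) a naive pooled linear model of the exposure that
    ignores study membership; (b) batch correction followed by per-study
    models pooled by random-effects meta-analysis.  FPR is the fraction of
    features with nominal p < 0.05; the exposure is truly null.
    """
    rows = []
    for s in _child_seeds(seed, n_replicates):
        sc = SimulationScenario(
            kind="confounded_null", n_batches=n_batches,
            samples_per_batch=samples_per_batch, n_features=n_features,
            pct_spiked=pct_spiked, effect_batch=effect_batch,
            imbalance=imbalance, seed=s,
        )
        table, meta, _ = make_scenario(sc)

        naive = fit_study_model(table, meta, "exposure", study_id="pooled")
        from scipy import stats as _st
        p_naive = [2 * _st.norm.sf(abs(e.beta / e.se)) for e in naive]

        corrected = correct(table, meta)
        res = run_meta_da(corrected, meta, "exposure", method="random")
        rows.append({
            "seed": s,
            "fpr_naive": false_positive_rate(p_naive),
            "fpr_mmuphin": false_positive_rate(res.results["p"].to_numpy()),
        })
    return pd.DataFrame(rows)


def correction_benchmark(
    seed: int = 0,
    n_replicates: int = 20,
    n_batches: int = 4,
    samples_per_batch: int = 100,
    n_features: int = 1000,
    pct_spiked: float = 0.05,
    effect_batch: float = 10.0,
    effect_controls: float = 10.0,
) -> pd.DataFrame:
    """Pre- vs post-correction PERMANOVA R^2 for batch and control variables.

    Correction models the positive and negative control covariates, as a
    user would when protecting known biology; success is a reduced batch
    R^2 with positive-control R^2 retained and negative-control R^2 not
    inflated.
    """
    covs = ["pos_binary", "pos_continuous", "neg_binary"]
    rows = []
    for s in _child_seeds(seed, n_replicates):
        sc = SimulationScenario(
            kind="batch_covariate", n_batches=n_batches,
            samples_per_batch=samples_per_batch, n_features=n_features,
            pct_spiked=pct_spiked, effect_batch=effect_batch,
            effect_binary=effect_controls, effect_continuous=effect_controls,
            seed=s,
        )
        table, meta, _ = make_scenario(sc)
        corrected = correct(table, meta, covariate_names=covs)
        # reference null: a fresh random binary variable the correction
        # never saw, giving the chance-level R^2 on each stage's geometry
        null_var = np.random.default_rng(s + 1).integers(0, 2, table.shape[0]).astype(str)
        row = {"seed": s}
        for stage, t in (("pre", table), ("post", corrected)):
            D = _bc(t)
            row[f"{stage}_batch"] = permanova_r2(D, meta.batch, n_perm=0).r2
            for v in covs:
                row[f"{stage}_{v}"] = permanova_r2(D, meta.data[v], n_perm=0).r2
            row[f"{stage}_null"] = permanova_r2(D, null_var, n_perm=0).r2
        rows.append(row)
    return pd.DataFrame(rows)


def discrete_benchmark(
    seed: int = 0,
    n_replicates: int = 20,
    true_k: int = 3,
    n_batches: int = 2,
    samples_per_batch: int = 250,
    n_features: int = 1000,
    pct_spiked: float = 0.20,
    effect_batch: float = 10.0,
    effect_cluster: float = 10.0,
    k_range: range | list[int] = range(2, 7),
    n_iter: int = 20,
    arms: tuple[str, ...] = ("pre", "post"),
) -> pd.DataFrame:
    """Cluster-number recovery by prediction strength, pre/post correction.

    Batch correction uses only the batch label (the planted cluster
    structure is unknown to it); success means the k maximizing average
    prediction strength on the pooled samples equals the planted k.
    """
    rows = []
    for s in _child_seeds(seed, n_replicates):
        sc = SimulationScenario(
            kind="discrete_clusters", n_batches=n_batches,
            samples_per_batch=samples_per_batch, n_features=n_features,
            pct_spiked=pct_spiked, effect_batch=effect_batch,
            effect_cluster=effect_cluster, n_clusters=true_k, seed=s,
        )
        table, meta, truth = make_scenario(sc)
        row = {"seed": s, "true_k": true_k}
        for arm in arms:
            t = table if arm == "pre" else correct(table, meta)
            ev = prediction_strength(_bc(t), k_range, n_iter=n_iter, seed=s)
            row[f"k_{arm}"] = ev.select_k()
            row[f"success_{arm}"] = int(ev.select_k() == true_k)
        rows.append(row)
    return pd.DataFrame(rows)


def continuous_benchmark(
    seed: int = 0,
    n_replicates: int = 20,
    n_batches: int = 4,
    samples_per_batch: int = 100,
    n_features: int = 1000,
    pct_spiked: float = 0.20,
    effect_batch: float = 10.0,
    effect_gradient: float = 10.0,
    threshold_v: float = 0.80,
    threshold_s: float = 0.7,
    arms: tuple[str, ...] = ("pre", "post"),
) -> pd.DataFrame:
    """Gradient recovery by consensus loadings, pre/post correction.

    Each batch serves as one training study for per-study PCA; the
    strongest consensus module's score, assigned on the pooled table, is
    correlated (sign-invariant) with the planted Uniform(-1,1) gradient.
    Replicates where no cross-study module forms score zero.
    """
    rows = []
    for s in _child_seeds(seed, n_replicates):
        sc = SimulationScenario(
            kind="continuous_gradient", n_batches=n_batches,
            samples_per_batch=samples_per_batch, n_features=n_features,
            pct_spiked=pct_spiked, effect_batch=effect_batch,
            effect_gradient=effect_gradient, seed=s,
        )
        table, meta, truth = make_scenario(sc)
        gradient = np.asarray(truth["gradient"])
        row = {"seed": s}
        for arm in arms:
            t = table if arm == "pre" else correct(table, meta)
            studies = {
                b: FeatureTable(t.data.loc[(meta.batch == b).to_numpy()])
                for b in sorted(meta.batch.unique())
            }
            consensus, _ = discover_gradients(studies, threshold_v, threshold_s)
            if not consensus:
                row[f"pearson_abs_{arm}"] = 0.0
                row[f"spearman_abs_{arm}"] = 0.0
                continue
            score = assign_scores(t, consensus[0])
            rec = gradient_recovery(gradient, score)
            row[f"pearson_abs_{arm}"] = rec["pearson_abs"]
            row[f"spearman_abs_{arm}"] = rec["spearman_abs"]
        rows.append(row)
    return pd.DataFrame(rows)
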