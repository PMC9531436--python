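import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mmuphin.data_model import FeatureTable, SampleMetadata, tss_normalize, arcsin_sqrt_transform
from mmuphin.meta_da import (
    MetaDAError,
    StudyEffect,
    bh_adjust,
    contrast_models,
    dersimonian_laird_tau2,
    fit_study_model,
    moderator_test,
    pool_effects,
    run_meta_da,
    _reml_tau2,
)


def _dataset(rng, n=40, P=6, batches=("s1",)):
    values = np.exp(rng.normal(3, 1, (n, P)))
    idx = [f"s{i}" for i in range(n)]
    table = FeatureTable(pd.DataFrame(values, index=idx, columns=[f"f{j}" for j in range(P)]))
    meta = SampleMetadata(pd.DataFrame({
        "batch": np.resize(list(batches), n),
        "exposure": np.resize(["ctrl", "case"], n),
        "age": rng.normal(40, 10, n),
    }, index=idx))
    return table, meta


class TestStudyModel:
    def test_binary_exposure_matches_two_sample_closed_form(self, rng):
        table, meta = _dataset(rng)
        effects = fit_study_model(table, meta, "exposure")
        Y = arcsin_sqrt_transform(tss_normalize(table))
        x = (meta.data["exposure"] == "ctrl").to_numpy()  # "ctrl" is level 2 alphabetically
        for e in effects:
            j = table.feature_ids.index(e.feature)
            y1, y0 = Y[x, j], Y[~x, j]
            diff = y1.mean() - y0.mean()
            sp2 = (((y1 - y1.mean()) ** 2).sum() + ((y0 - y0.mean()) ** 2).sum()) / (len(x) - 2)
            se = np.sqrt(sp2 * (1 / x.sum() + 1 / (~x).sum()))
            assert e.beta == pytest.approx(diff, abs=1e-10)
            assert e.se == pytest.approx(se, rel=1e-10)

    def test_constant_exposure_yields_no_effects(self, rng):
        table, meta = _dataset(rng)
        meta.data["exposure"] = "ctrl"
        assert fit_study_model(table, meta, "exposure") == []

    def test_all_zero_feature_is_absent(self, rng):
        table, meta = _dataset(rng)
        table.data.iloc[:, 2] = 0.0
        effects = fit_study_model(table, meta, "exposure")
        assert table.feature_ids[2] not in {e.feature for e in effects}

    def test_random_intercept_model_used_for_repeats(self, rng):
        table, meta = _dataset(rng, n=60)
        meta.data["subject"] = np.repeat([f"p{i}" for i in range(20)], 3)
        effects = fit_study_model(table, meta, "exposure", random_group="subject")
        assert effects and all(e.model == "random-intercept" for e in effects)

    def test_power_on_spiked_feature(self):
        # exposure shifts feature 0 strongly: effect detected in most replicates
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            table, meta = _dataset(rng, n=200, P=5)
            x = (meta.data["exposure"] == "case").to_numpy()
            table.data.iloc[x, 0] *= 8.0
            effects = fit_study_model(table, meta, "exposure")
            e0 = next(e for e in effects if e.feature == "f0")
            hits += abs(e0.beta / e0.se) > 1.96
        assert hits >= 9


class TestPooling:
    def test_single_study_passthrough(self):
        e = StudyEffect("s1", "f", 0.3, 0.1, 50)
        pooled = pool_effects([e], method="random")
        assert pooled.beta == pytest.approx(0.3)
        assert pooled.tau2 == 0.0 and pooled.k == 1

    def test_fixed_effect_matches_inverse_variance_closed_form(self, rng):
        for _ in range(5):
            betas = rng.normal(0, 1, 4)
            ses = rng.uniform(0.05, 0.5, 4)
            effects = [StudyEffect("s", "f", b, s, 10) for b, s in zip(betas, ses)]
            pooled = pool_effects(effects, method="fixed")
            w = 1 / ses**2
            assert pooled.beta == pytest.approx(np.sum(w * betas) / w.sum(), abs=1e-12)
            assert pooled.se == pytest.approx(np.sqrt(1 / w.sum()), abs=1e-12)
            assert np.isclose(pooled.weights.sum(), 1.0)

    def test_identical_studies_have_zero_heterogeneity(self):
        effects = [StudyEffect(f"s{i}", "f", 0.2, 0.05, 30) for i in range(2)]
        pooled = pool_effects(effects, method="random")
        assert pooled.tau2 == pytest.approx(0.0, abs=1e-8)
        assert pooled.beta == pytest.approx(0.2)

    def test_reml_matches_profile_likelihood_grid(self):
        # dense grid oracle for the restricted likelihood
        def grid_reml(y, v):
            grid = np.linspace(0, 5 * np.var(y, ddof=1), 40001)
            def rll(t2):
                w = 1 / (v + t2)
                mu = np.sum(w * y) / w.sum()
                return -0.5 * (np.sum(np.log(v + t2)) + np.log(w.sum())
                               + np.sum(w * (y - mu) ** 2))
            vals = [rll(t) for t in grid]
            return grid[int(np.argmax(vals))]

        rng = np.random.default_rng(3)
        for _ in range(20):
            k = rng.integers(3, 8)
            y = rng.normal(0.1, 0.3, k)
            v = rng.uniform(0.01, 0.1, k) ** 2 + 0.001
            tau2 = _reml_tau2(y, v)
            assert tau2 == pytest.approx(grid_reml(y, v), abs=1e-4)

    def test_known_three_study_example(self):
        effects = [StudyEffect(f"s{i}", "f", b, 0.05, 20)
                   for i, b in enumerate([0.1, 0.2, 0.3])]
        fixed = pool_effects(effects, method="fixed")
        assert fixed.beta == pytest.approx(0.2, abs=1e-12)
        random = pool_effects(effects, method="random")
        assert random.tau2 > 0
        assert random.se > fixed.se

    def test_dersimonian_laird_nonnegative(self, rng):
        y = rng.normal(0, 0.2, 5)
        v = rng.uniform(0.01, 0.05, 5)
        assert dersimonian_laird_tau2(y, v) >= 0


class TestModerator:
    def test_constant_moderator_rejected(self):
        eff = {"a": [StudyEffect("a", "f", 0.1, 0.05, 10)],
               "b": [StudyEffect("b", "f", 0.2, 0.05, 10)]}
        with pytest.raises(MetaDAError):
            moderator_test(eff, {"a": 1, "b": 1})

    def test_saturated_two_strata_closed_form(self):
        eff = {"a": [StudyEffect("a", "f", 0.10, 0.05, 10)],
               "b": [StudyEffect("b", "f", 0.45, 0.05, 10)]}
        out = moderator_test(eff, {"a": 0, "b": 1})
        assert out.loc[0, "beta1"] == pytest.approx(0.35, abs=1e-10)
        assert out.loc[0, "beta0"] == pytest.approx(0.10, abs=1e-10)

    def test_recovers_injected_interaction(self):
        rng = np.random.default_rng(8)
        delta, se = 0.1, 0.02
        cover = 0
        for _ in range(20):
            eff = {}
            mod = {}
            for i in range(6):
                level = i % 2
                b = 0.05 + delta * level + rng.normal(0, se)
                eff[f"s{i}"] = [StudyEffect(f"s{i}", "f", b, se, 30)]
                mod[f"s{i}"] = level
            out = moderator_test(eff, mod)
            cover += abs(out.loc[0, "beta1"] - delta) < 2 * out.loc[0, "se1"]
        assert cover >= 18


class TestBH:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_edge_cases(self):
        assert bh_adjust([0.07])[0] == pytest.approx(0.07)
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)
        out = bh_adjust([0.01, np.nan])
        assert np.isnan(out[1]) and out[0] == pytest.approx(0.01)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_invariants(self, pvals):
        q = bh_adjust(pvals)
        assert (q >= np.asarray(pvals) - 1e-12).all() and (q <= 1 + 1e-12).all()
        perm = np.random.default_rng(0).permutation(len(pvals))
        q_perm = bh_adjust(np.asarray(pvals)[perm])
        np.testing.assert_allclose(q_perm, q[perm], atol=1e-12)


class TestOrchestration:
    def test_two_identical_studies_tighten_se(self, rng):
        table, meta = _dataset(rng, n=80)
        single = fit_study_model(table, meta, "exposure")
        doubled = FeatureTable(pd.concat([
            table.data,
            table.data.set_axis([f"r{i}" for i in range(80)], axis=0),
        ]))
        meta2 = SampleMetadata(pd.concat([
            meta.data.assign(batch="s1"),
            meta.data.assign(batch="s2").set_axis([f"r{i}" for i in range(80)], axis=0),
        ]))
        res = run_meta_da(doubled, meta2, "exposure", method="fixed")
        for e in single:
            row = res.results[res.results.feature == e.feature].iloc[0]
            assert row.beta == pytest.approx(e.beta, abs=1e-10)
            assert row.se == pytest.approx(e.se / np.sqrt(2), rel=1e-10)

    def test_contrast_models_monotone_trend(self):
        rng = np.random.default_rng(21)
        n, P, d = 300, 4, 0.15
        levels = np.resize(["L1", "L2", "L3"], n)
        # build transformed-scale shifts via multiplicative count spikes
        values = np.exp(rng.normal(4, 0.3, (n, P)))
        shift = {"L1": 1.0, "L2": 2.0, "L3": 4.0}
        values[:, 0] *= np.array([shift[l] for l in levels])
        idx = [f"s{i}" for i in range(n)]
        table = FeatureTable(pd.DataFrame(values, index=idx,
                                          columns=[f"f{j}" for j in range(P)]))
        meta = SampleMetadata(pd.DataFrame({
            "batch": np.resize(["s1", "s2"], n), "sev": levels}, index=idx))
        out = contrast_models(table, meta, "sev", ("L1", "L2", "L3"))
        b21 = out["L2_vs_L1"].set_index("feature").loc["f0", "beta"]
        b31 = out["L3_vs_L1"].set_index("feature").loc["f0", "beta"]
        assert 0 < b21 < b31
        # incremental-effect FDR restricted to features flagged pairwise
        joint = out["L3_incremental"]
        flagged = set(out["L2_vs_L1"].query("q < 0.05").feature) | \
            set(out["L3_vs_L1"].query("q < 0.05").feature)
        has_q = set(joint[joint.q2.notna()].feature)
        assert has_q <= flagged

    def test_null_contrasts_are_null(self, rng):
        table, meta = _dataset(rng, n=120, batches=("s1", "s2"))
        meta.data["sev"] = np.resize(["L1", "L2", "L3"], 120)
        out = contrast_models(table, meta, "sev", ("L1", "L2", "L3"))
        assert (out["L2_vs_L1"].q > 0.05).all()
        assert (out["L3_vs_L1"].q > 0.05).all()
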