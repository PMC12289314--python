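"""Harness: folds, metrics, baselines, grid enumeration, the subsampled
metric-learning protocol, and the comparison statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import patsim.autoencoder as ae
import patsim.evaluation as ev
import patsim.preprocess as pp
from patsim.cohort import CohortSpec, generate_cohort


@pytest.fixture(scope="module")
def tiny_grid():
    return ev.GridSpec(learning_rates=(1e-2,), optimizers=("adam",),
                       latent_ratios=(0.15,), activations=("sigmoid",),
                       variants=("AE",), ks=(5,), n_folds=2, seed=0,
                       max_epochs=30, patience=5)


@pytest.fixture(scope="module")
def signal_cohort():
    spec = CohortSpec(n_patients=360, n_medications=15, n_procedures=15,
                      n_labs=6, latent_dim_true=4, label_signal_strength=4.0,
                      prevalence_aki=0.25, prevalence_mortality=0.25,
                      noise_sd=0.2, outlier_rate=0.0, seed=2)
    return generate_cohort(spec)


class TestFolds:
    def test_partition_and_sizes(self):
        y = np.arange(10) % 2
        folds = ev.stratified_kfold(y, 5, seed=0)
        assert sorted(np.bincount(folds)) == [2] * 5
        assert set(folds) == set(range(5))

    def test_stratification_exact(self):
        y = np.r_[np.ones(20), np.zeros(80)].astype(int)
        folds = ev.stratified_kfold(y, 5, seed=1)
        for f in range(5):
            assert y[folds == f].sum() == 4

    def test_small_class_warns(self):
        y = np.r_[np.ones(2), np.zeros(50)].astype(int)
        with pytest.warns(UserWarning, match="fewer members"):
            ev.stratified_kfold(y, 5, seed=0)


class TestMetrics:
    def test_f1_formula(self):
        # TP=2, FP=1, FN=1 -> F1 = 2/3
        y_true = np.array([1, 1, 1, 0, 0])
        y_pred = np.array([1, 1, 0, 1, 0])
        m = ev.classification_metrics(y_true, y_pred, y_pred.astype(float))
        assert m["f1"] == pytest.approx(2 / 3)

    def test_perfect_ranking_auroc(self):
        y = np.array([0, 0, 1, 1])
        s = np.array([0.1, 0.2, 0.8, 0.9])
        m = ev.classification_metrics(y, (s > 0.5).astype(int), s)
        assert m["auroc"] == 1.0 and m["auprc"] == 1.0

    def test_auroc_equals_pairwise_concordance(self, rng):
        y = rng.integers(0, 2, 200)
        s = rng.random(200)
        s[:50] = np.round(s[:50], 1)  # force some ties
        m = ev.classification_metrics(y, (s > 0.5).astype(int), s)
        pos, neg = s[y == 1], s[y == 0]
        wins = (pos[:, None] > neg[None, :]).sum()
        ties = (pos[:, None] == neg[None, :]).sum()
        assert m["auroc"] == pytest.approx(
            (wins + 0.5 * ties) / (len(pos) * len(neg)), abs=1e-10)

    def test_single_class_flagged(self):
        m = ev.classification_metrics(np.ones(5, dtype=int), np.ones(5, dtype=int),
                                      np.ones(5))
        assert np.isnan(m["auroc"]) and np.isnan(m["auprc"])


class TestPCABaseline:
    def test_constructed_spectrum_keeps_one_component(self, rng):
        # one direction with 99.5% of variance, one with 0.5%
        n = 400
        basis = np.linalg.qr(rng.standard_normal((6, 6)))[0]
        scores = np.column_stack([np.sqrt(199) * rng.standard_normal(n),
                                  rng.standard_normal(n)])
        X = scores @ basis[:2]
        tr, te, ncomp = ev.pca_baseline(X[:300], X[300:], 0.99)
        assert ncomp == 1 and tr.shape[1] == 1

    def test_full_variance_keeps_all_nonzero(self, rng):
        X = rng.standard_normal((50, 4)) @ rng.standard_normal((4, 6))
        _, _, ncomp = ev.pca_baseline(X[:40], X[40:], 1.0)
        assert ncomp == 4  # rank-4 data

    def test_reconstruction_error_bound(self, rng):
        X = rng.standard_normal((200, 10))
        tr, _, ncomp = ev.pca_baseline(X[:150], X[50:], 0.99)
        Xc = X[:150] - X[:150].mean(axis=0)
        total_var = (Xc ** 2).sum()
        resid = total_var - (tr ** 2).sum()
        assert resid <= 0.01 * total_var + 1e-9


class TestStatistics:
    def test_hand_computed_p_value(self):
        a = np.array([0.2, 0.4, 0.6])
        b = np.array([0.1, 0.2, 0.3])
        p = ev.paired_ttest_onetailed(a, b)
        t = 0.2 / (0.1 / np.sqrt(3))
        assert t == pytest.approx(3.4641, abs=1e-4)
        assert p == pytest.approx(0.0371, abs=2e-4)

    def test_degenerate_conventions(self):
        x = np.array([0.25, 0.5, 0.75])  # exactly representable increments
        assert ev.paired_ttest_onetailed(x, x) == 0.5
        assert ev.paired_ttest_onetailed(x + 0.25, x) == 0.0
        assert ev.paired_ttest_onetailed(x - 0.25, x) == 1.0

    def test_matches_reference_implementation(self, rng):
        for _ in range(100):
            a, b = rng.random(8), rng.random(8)
            expected = stats.ttest_rel(a, b, alternative="greater").pvalue
            assert ev.paired_ttest_onetailed(a, b) == pytest.approx(
                expected, abs=1e-10)

    def test_spearman_signs_and_oracle(self, rng):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert ev.spearman_concordance(x, x ** 3) == 1.0
        assert ev.spearman_concordance(x, -x) == -1.0
        a, b = rng.random(30), rng.random(30)
        ra = stats.rankdata(a)
        rb = stats.rankdata(b)
        manual = np.corrcoef(ra, rb)[0, 1]
        assert ev.spearman_concordance(a, b) == pytest.approx(manual, abs=1e-12)

    def test_constant_input_flagged(self):
        with pytest.warns(UserWarning, match="constant"):
            assert np.isnan(ev.spearman_concordance(np.ones(5),
                                                    np.arange(5.0)))

    def test_top5_boundary_and_dominance(self):
        recs = []
        for cid in range(5):
            for fold in range(2):
                recs.append({"variant": "AE", "config_id": f"c{cid}",
                             "target": "aki", "k": 5, "fold": fold,
                             "f1": 0.3 + 0.01 * cid})
        df = pd.DataFrame(recs)
        top = ev.top5_summary(df)
        assert top.loc[0, "mean"] == pytest.approx(np.mean([0.3 + 0.01 * c
                                                            for c in range(5)]))
        # one dominant extra config shifts the top-5 mean by excess/5
        extra = pd.DataFrame([{"variant": "AE", "config_id": "c9",
                               "target": "aki", "k": 5, "fold": f,
                               "f1": 0.5} for f in range(2)])
        top2 = ev.top5_summary(pd.concat([df, extra], ignore_index=True))
        # top5 now c9 + c1..c4 (c0 drops out)
        expect = np.mean([0.5, 0.31, 0.32, 0.33, 0.34])
        assert top2.loc[0, "mean"] == pytest.approx(expect)

    def test_top5_ranking_matches_sort_oracle(self, rng):
        recs = [{"variant": "AE", "config_id": f"c{i:02d}", "target": "aki",
                 "k": 5, "fold": 0, "f1": float(v)}
                for i, v in enumerate(rng.random(12))]
        df = pd.DataFrame(recs)
        top = ev.top5_summary(df)
        best5 = np.sort(df["f1"].to_numpy())[-5:]
        assert top.loc[0, "mean"] == pytest.approx(best5.mean())


class TestGrid:
    def test_default_grid_is_168_per_variant(self):
        assert ev.GridSpec().size == 168
        assert len(ev.GridSpec().configs("DAE")) == 168

    def test_reduced_axes_product(self):
        g = ev.GridSpec(learning_rates=(1e-3, 1e-2), optimizers=("adam",),
                        latent_ratios=(0.15, 0.5), activations=("sigmoid",))
        assert g.size == 4

    def test_config_ids_unique_and_stable(self):
        g = ev.GridSpec()
        ids = [ev.config_id(c) for c in g.configs("CAE")]
        assert len(set(ids)) == 168
        assert ids == [ev.config_id(c) for c in g.configs("CAE")]


class TestEvaluateConfig:
    def test_record_counts_and_ranges(self, signal_cohort, tiny_grid):
        cfg = tiny_grid.configs("AE")[0]
        recs = ev.evaluate_config(signal_cohort, cfg, tiny_grid)
        # folds x ks x targets for AE + raw + pca baselines
        per_method = tiny_grid.n_folds * len(tiny_grid.ks) * len(tiny_grid.targets)
        assert len(recs) == 3 * per_method
        assert set(recs["variant"]) == {"AE", "raw", "pca"}
        for col in ("f1", "auprc", "auroc"):
            vals = recs[col].dropna()
            assert ((vals >= 0) & (vals <= 1)).all()

    def test_deterministic_records(self, signal_cohort, tiny_grid):
        cfg = tiny_grid.configs("AE")[0]
        a = ev.evaluate_config(signal_cohort, cfg, tiny_grid,
                               include_baselines=False)
        b = ev.evaluate_config(signal_cohort, cfg, tiny_grid,
                               include_baselines=False)
        pd.testing.assert_frame_equal(a, b)

    def test_beats_chance_level_f1_on_strong_signal(self, signal_cohort):
        # adequately trained AE on a strong-signal cohort must beat the
        # analytic chance level: random guessing at the prevalence pi has
        # F1 = pi (precision = recall = pi for label-independent predictions)
        grid = ev.GridSpec(learning_rates=(1e-2,), optimizers=("adam",),
                           latent_ratios=(0.5,), activations=("sigmoid",),
                           variants=("AE",), ks=(5,), n_folds=2, seed=0,
                           max_epochs=200, patience=10, batch_size=64)
        cfg = grid.configs("AE")[0]
        recs = ev.evaluate_config(signal_cohort, cfg, grid,
                                  include_baselines=False)
        sub = recs[(recs["k"] == 5) & (recs["target"] == "aki")]
        pi = signal_cohort.labels_aki.mean()
        assert sub["f1"].mean() > pi

    def test_no_test_leakage_into_fitted_state(self, signal_cohort, tiny_grid):
        # mutating the test fold's rows must leave every fitted component
        # (preprocessor statistics, AE weights) bit-identical
        cfg = tiny_grid.configs("AE")[0]
        folds = ev._fold_assignment(signal_cohort, tiny_grid)
        mutated = signal_cohort.select_rows(np.arange(signal_cohort.n))
        rows = np.flatnonzero(folds == 0)
        vals = mutated.values[rows]
        vals[np.isfinite(vals)] *= 50.0
        mutated.values[rows] = vals
        a = ev.fit_fold(signal_cohort, cfg, 0, folds)
        b = ev.fit_fold(mutated, cfg, 0, folds)
        np.testing.assert_array_equal(a["fitted"].col_min, b["fitted"].col_min)
        np.testing.assert_array_equal(a["fitted"].winsor_hi, b["fitted"].winsor_hi)
        np.testing.assert_array_equal(a["model"].W, b["model"].W)
        np.testing.assert_array_equal(a["Z_tr"], b["Z_tr"])
        assert not np.allclose(a["Z_te"], b["Z_te"])  # test inputs did change

    def test_run_grid_enumerates_product(self, signal_cohort):
        g = ev.GridSpec(learning_rates=(1e-2,), optimizers=("adam",),
                        latent_ratios=(0.15, 0.5), activations=("sigmoid",),
                        variants=("AE", "DAE"), ks=(5,), n_folds=2,
                        max_epochs=15)
        recs = ev.run_grid(signal_cohort, g)
        ae_recs = recs[recs["variant"].isin(("AE", "DAE"))]
        assert ae_recs.groupby("variant")["config_id"].nunique().eq(2).all()


class TestMahalanobisExperiment:
    def test_full_sample_identity_reproduces_euclidean(self, signal_cohort,
                                                       tiny_grid):
        cfg = tiny_grid.configs("AE")[0]
        base = ev.evaluate_config(signal_cohort, cfg, tiny_grid,
                                  include_baselines=False)
        out = ev.mahalanobis_experiment(
            signal_cohort, {"AE": cfg}, sample_fraction=1.0, seed=9,
            grid=tiny_grid, methods=("euclidean",), k=5)
        a = (base[(base["k"] == 5)]
             .sort_values(["target", "fold"])[["f1", "auprc", "auroc"]]
             .reset_index(drop=True))
        b = (out[out["variant"] == "AE"]
             .sort_values(["target", "fold"])[["f1", "auprc", "auroc"]]
             .reset_index(drop=True))
        pd.testing.assert_frame_equal(a, b)

    def test_shared_subsample_and_metrics_run(self, signal_cohort, tiny_grid):
        cfgs = {"AE": tiny_grid.configs("AE")[0],
                "DAE": ae.AEConfig(variant="DAE", learning_rate=1e-2,
                                   max_epochs=30, seed=0)}
        out = ev.mahalanobis_experiment(
            signal_cohort, cfgs, sample_fraction=0.5, seed=4,
            grid=tiny_grid, methods=("euclidean", "lmnn"), k=5)
        assert set(out["variant"]) == {"raw", "AE", "DAE"}
        assert set(out["distance"]) == {"euclidean", "lmnn"}
        assert ((out["f1"] >= 0) & (out["f1"] <= 1)).all()

    def test_subsample_below_k_raises(self, signal_cohort, tiny_grid):
        cfg = tiny_grid.configs("AE")[0]
        with pytest.raises(ValueError, match="subsample"):
            ev.mahalanobis_experiment(signal_cohort, {"AE": cfg},
                                      sample_fraction=0.005, seed=1,
                                      grid=tiny_grid, k=5)


class TestSelectionAndConcordance:
    def _records(self, shift=0.0):
        recs = []
        for variant in ("AE", "DAE"):
            for i, ratio in enumerate((0.15, 0.5)):
                cid = f"lr0.01-adam-r{ratio:g}-sigmoid"
                for fold in range(2):
                    recs.append({"variant": variant, "config_id": cid,
                                 "fold": fold, "target": "aki", "k": 5,
                                 "distance": "euclidean",
                                 "f1": 0.3 + 0.1 * i + shift
                                 + (0.05 if variant == "DAE" else 0.0)})
        return pd.DataFrame(recs)

    def test_select_best_configs(self):
        g = ev.GridSpec(learning_rates=(1e-2,), optimizers=("adam",),
                        latent_ratios=(0.15, 0.5), activations=("sigmoid",),
                        variants=("AE", "DAE"))
        best = ev.select_best_configs(self._records(), g)
        assert best["AE"].latent_ratio == 0.5
        constrained = ev.select_best_configs(self._records(), g,
                                             latent_ratio=0.15)
        assert constrained["DAE"].latent_ratio == 0.15

    def test_site_concordance_perfect_monotone(self):
        rho = ev.site_concordance(self._records(), self._records(shift=0.1))
        assert rho == pytest.approx(1.0)
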