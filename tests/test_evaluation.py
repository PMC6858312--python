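import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oncotyper as ot
from oncotyper.evaluate import LeakageError, _assert_no_leakage, _row_hashes


class TestStratifiedFolds:
    def test_balanced_two_class_split(self):
        y = np.repeat(["a", "b"], 50)
        plan = ot.stratified_folds(y, 10, seed=0)
        for fold in plan.folds:
            assert len(fold) == 10
            assert np.sum(y[fold] == "a") == 5

    def test_rare_class_spread_across_distinct_folds(self):
        y = np.array(["rare"] * 3 + ["common"] * 97)
        plan = ot.stratified_folds(y, 10, seed=1)
        holding = [i for i, fold in enumerate(plan.folds) if (y[fold] == "rare").any()]
        assert len(holding) == 3

    def test_same_seed_same_plan(self):
        y = np.repeat(["a", "b", "c"], 17)
        p1 = ot.stratified_folds(y, 5, seed=42)
        p2 = ot.stratified_folds(y, 5, seed=42)
        for f1, f2 in zip(p1.folds, p2.folds):
            np.testing.assert_array_equal(f1, f2)

    def test_folds_partition_all_samples(self):
        y = np.repeat(["a", "b", "c"], [11, 7, 5])
        plan = ot.stratified_folds(y, 4, seed=0)
        all_idx = np.sort(np.concatenate(plan.folds))
        np.testing.assert_array_equal(all_idx, np.arange(len(y)))
        sizes = [len(f) for f in plan.folds]
        assert max(sizes) - min(sizes) <= 1

    def test_more_folds_than_samples_raises(self):
        with pytest.raises(ValueError):
            ot.stratified_folds(np.array(["a", "b"]), 3, seed=0)


class TestClassMetrics:
    def test_perfect_prediction_scores_100(self):
        y = np.array(["a", "b", "a", "b"])
        table = ot.class_metrics(y, y, ["a", "b"])
        assert (table.loc[["a", "b"], ["precision", "recall", "f1"]] == 100.0).all().all()
        assert table.loc["Total", "accuracy"] == 100.0

    def test_harmonic_f1_examples(self):
        assert ot.harmonic_f1(88.36, 94.39) == pytest.approx(91.27, abs=0.01)
        assert ot.harmonic_f1(0.0, 0.0) == 0.0

    def test_fold_averaged_accuracy_differs_from_pooled_recall(self):
        # class "a": fold 0 gets 1/2 right, fold 1 gets 1/1 right
        y_true = np.array(["a", "a", "b", "a", "b"])
        y_pred = np.array(["a", "b", "b", "a", "b"])
        folds = np.array([0, 0, 0, 1, 1])
        table = ot.class_metrics(y_true, y_pred, ["a", "b"], fold_ids=folds)
        assert table.loc["a", "accuracy"] == pytest.approx(75.0)  # mean(1/2, 1/1)
        assert table.loc["a", "recall"] == pytest.approx(100 * 2 / 3)

    def test_macro_f1_is_mean_of_per_class_f1(self):
        y_true = np.array(["a", "a", "b", "b", "c", "c"])
        y_pred = np.array(["a", "b", "b", "b", "c", "a"])
        table = ot.class_metrics(y_true, y_pred, ["a", "b", "c"])
        assert table.loc["Total", "f1"] == pytest.approx(
            table.loc[["a", "b", "c"], "f1"].mean()
        )

    def test_label_outside_declared_set_raises(self):
        with pytest.raises(ValueError, match="outside"):
            ot.class_metrics(["a"], ["z"], ["a", "b"])


class TestAgreement:
    def test_enumerated_four_outcomes(self):
        table = ot.agreement_table([True, True, False, False], [True, False, True, False])
        assert table.pct_a == 50.0
        assert table.pct_b == 50.0
        assert table.pct_both == 25.0
        assert table.pct_either == 75.0
        assert table.pct_only_a == 25.0
        assert table.pct_only_b == 25.0

    def test_identical_vectors_have_no_exclusive_region(self):
        v = [True, False, True]
        table = ot.agreement_table(v, v)
        assert table.pct_both == table.pct_a
        assert table.pct_only_a == 0.0 and table.pct_only_b == 0.0

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            ot.agreement_table([True], [True, False])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=1, max_size=200))
    def test_inclusion_exclusion_identities_hold_exactly(self, pairs):
        a = [p[0] for p in pairs]
        b = [p[1] for p in pairs]
        t = ot.agreement_table(a, b)
        assert t.pct_either == pytest.approx(t.pct_a + t.pct_b - t.pct_both, abs=1e-12)
        assert t.pct_only_a == pytest.approx(t.pct_a - t.pct_both, abs=1e-12)
        assert t.pct_only_b == pytest.approx(t.pct_b - t.pct_both, abs=1e-12)
        for v in (t.pct_a, t.pct_b, t.pct_both, t.pct_either, t.pct_only_a, t.pct_only_b):
            assert 0.0 <= v <= 100.0


class TestLeakageGuard:
    def test_overlapping_rows_abort(self):
        X = np.arange(12, dtype=float).reshape(4, 3)
        hashes = _row_hashes(X[2:])
        with pytest.raises(LeakageError):
            _assert_no_leakage(X, hashes, "training")

    def test_disjoint_rows_pass(self):
        X = np.arange(12, dtype=float).reshape(4, 3)
        _assert_no_leakage(X[:2], _row_hashes(X[2:]), "training")


class TestInnerSelectConfig:
    def test_single_candidate_is_chosen_without_search(self):
        X = np.random.default_rng(0).normal(size=(30, 10))
        y = np.repeat(["a", "b"], 15)
        plan = ot.stratified_folds(y, 3, seed=0)
        method, k, table = ot.inner_select_config(X, y, ["lsvc"], [4], plan)
        assert (method, k) == ("lsvc", 4)
        assert len(table) == 1

    def test_empty_grid_raises(self):
        X = np.zeros((10, 3))
        y = np.repeat(["a", "b"], 5)
        plan = ot.stratified_folds(y, 2, seed=0)
        with pytest.raises(ValueError, match="empty"):
            ot.inner_select_config(X, y, [], [], plan)

    def test_prefers_small_k_when_signal_is_concentrated(self, small_mlp_config):
        # 20 informative features among pure noise: the full-dimension model
        # dilutes them, so the inner loop should usually choose k = 20.
        n, d, n_inf = 210, 150, 20
        choices = []
        for seed in (0, 1, 2):
            rng = np.random.default_rng(seed)
            y = np.array([f"c{i % 3}" for i in range(n)])
            X = rng.normal(0, 1.0, size=(n, d))
            for j in range(n_inf):
                X[:, j] += np.where(y == f"c{j % 3}", 1.0, 0.0)
            plan = ot.stratified_folds(y, 3, seed=seed)
            method, k, _ = ot.inner_select_config(
                X, y, ["lsvc"], [n_inf, d], plan, seed=seed,
                mlp_config=small_mlp_config, rf_config=ot.RandomForestConfig(n_trees=50),
            )
            assert method == "lsvc"
            choices.append(k)
        assert sum(1 for k in choices if k == n_inf) >= 2


class TestNestedCV:
    @pytest.fixture(scope="class")
    def tiny_report(self, tiny_cohort, request):
        mlp = ot.MlpConfig(
            hidden_layers=2, units_per_layer=64, learning_rate=1e-3,
            batch_size=32, max_epochs=50, seed=0,
        )
        return ot.nested_cv(
            tiny_cohort["matrix"], tiny_cohort["labels"], methods=("lsvc",),
            k_grid=[40], seed=5, n_outer=5, n_inner=3,
            mlp_config=mlp, rf_config=ot.RandomForestConfig(n_trees=100),
        )

    def test_every_sample_predicted_exactly_once(self, tiny_report, tiny_cohort):
        assert len(tiny_report.predictions["ensemble"]) == len(tiny_cohort["matrix"].samples)
        assert not any(p is None for p in tiny_report.predictions["ensemble"])
        assert set(np.unique(tiny_report.fold_ids)) == set(range(5))

    def test_planted_signal_is_learned(self, tiny_report):
        assert tiny_report.accuracy("ensemble") > 0.9

    def test_metrics_recomputable_from_predictions(self, tiny_report):
        table = tiny_report.metrics("ensemble")
        assert table.loc["Total", "accuracy"] == pytest.approx(
            100.0 * tiny_report.accuracy("ensemble")
        )

    def test_seeded_run_is_reproducible(self, tiny_cohort, tiny_report):
        mlp = ot.MlpConfig(
            hidden_layers=2, units_per_layer=64, learning_rate=1e-3,
            batch_size=32, max_epochs=50, seed=0,
        )
        again = ot.nested_cv(
            tiny_cohort["matrix"], tiny_cohort["labels"], methods=("lsvc",),
            k_grid=[40], seed=5, n_outer=5, n_inner=3,
            mlp_config=mlp, rf_config=ot.RandomForestConfig(n_trees=100),
        )
        np.testing.assert_array_equal(
            again.predictions["ensemble"], tiny_report.predictions["ensemble"]
        )
        np.testing.assert_allclose(
            again.probabilities["mlp"], tiny_report.probabilities["mlp"]
        )


class TestAblation:
    def test_five_prefixes_in_order(self, tiny_cohort):
        results = ot.ablation_study(
            tiny_cohort["matrix"], tiny_cohort["labels"], seed=0, n_folds=3, n_trees=50
        )
        assert len(results) == 5
        assert results[0][0] == ("profile",)
        assert results[-1][0] == ("profile", "rates", "spectra", "scna", "signatures")

    def test_unknown_group_raises(self, tiny_cohort):
        with pytest.raises(ValueError, match="expression"):
            ot.ablation_study(
                tiny_cohort["matrix"], tiny_cohort["labels"], group_order=["expression"]
            )

    def test_signature_only_signal_jumps_when_signatures_added(self):
        # Disable driver and copy-number planting so the 96-context block is
        # the only planted signal; order the groups so that block comes last
        # after blocks with no class information (the spectra block, being the
        # signatures' six-class marginal, would leak part of the signal if it
        # preceded them).
        config = dataclasses.replace(
            ot.default_config("tiny"),
            driver_mutation_prob=0.0,
            cna_log2_shift_mean=0.0,
            cna_log2_shift_sd=0.0,
            samples_per_type=40,
        )
        variants, cnv, labels, _ = ot.simulate_cohort(config)
        matrix = ot.assemble_matrix(variants, cnv, labels, ot.schema_for(config))
        results = ot.ablation_study(
            matrix, labels, group_order=["profile", "rates", "scna", "signatures"],
            seed=0, n_folds=3, n_trees=100,
        )
        acc = dict((g[-1], a) for g, a in results)
        assert acc["signatures"] - acc["scna"] >= 0.10

    def test_single_group_prefix_equals_plain_cv_on_block(self, tiny_cohort):
        results = ot.ablation_study(
            tiny_cohort["matrix"], tiny_cohort["labels"],
            group_order=["signatures"], seed=3, n_folds=3, n_trees=50,
        )
        assert len(results) == 1 and results[0][0] == ("signatures",)


class TestImportanceAndFiltering:
    def test_scores_non_increasing_and_full_permutation(self, tiny_cohort):
        matrix, labels = tiny_cohort["matrix"], tiny_cohort["labels"]
        ranked = ot.rank_importance(matrix, labels, top_n=matrix.schema.dimension,
                                    seed=0, n_trees=50)
        names = [n for n, _ in ranked]
        scores = [s for _, s in ranked]
        assert sorted(names) == sorted(matrix.schema.columns)
        assert all(a >= b for a, b in zip(scores, scores[1:]))

    def test_min_samples_one_is_identity(self, tiny_cohort):
        matrix, labels = tiny_cohort["matrix"], tiny_cohort["labels"]
        m2, l2 = ot.filter_by_class_size(matrix, labels, 1)
        assert m2.samples == matrix.samples
        assert dict(l2.mapping) == dict(labels.mapping)

    def test_class_size_thresholds(self):
        config = dataclasses.replace(
            ot.default_config("tiny"), samples_per_type=(300, 150, 50),
            n_mut_genes=50, n_cnv_genes=20, drivers_per_type=2, cna_genes_per_type=2,
        )
        variants, cnv, labels, _ = ot.simulate_cohort(config)
        matrix = ot.assemble_matrix(variants, cnv, labels, ot.schema_for(config))
        m2, l2 = ot.filter_by_class_size(matrix, labels, 100)
        assert len(m2.samples) == 450 and len(l2.labels) == 2
        with pytest.raises(ValueError):
            ot.filter_by_class_size(matrix, labels, 200)  # one class survives
        with pytest.raises(ValueError):
            ot.filter_by_class_size(matrix, labels, 10_000)  # none survives
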