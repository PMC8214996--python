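"""SVM staging: splits, decision function, metrics, repeated hold-out."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pastage.augment import augment_set
from pastage.mrmr import build_feature_matrix, mrmr_rank
from pastage.preprocess import PreprocessOptions, preprocess_set
from pastage.svm_eval import (
    EvaluationReport,
    SVMHyperparameters,
    binary_decision_score,
    decision_score,
    evaluate,
    metrics_from_confusion,
    repeated_holdout,
    stratified_split,
    train_svm,
)
from pastage.synth import ClassTemplate, StudyDesign, default_templates, generate_dataset
from pastage.wpd import extract_aa2_features


def blobs_frame(rng, n_per_class=40, n_classes=3, spread=0.5, sep=5.0) -> pd.DataFrame:
    rows = []
    for c in range(n_classes):
        center = np.array([sep * c, -sep * c])
        for i in range(n_per_class):
            x = center + rng.normal(0, spread, 2)
            rows.append({"f1": x[0], "f2": x[1], "label": f"c{c}", "origin_id": f"c{c}-o{i // 4}", "id": f"c{c}-{i}"})
    return pd.DataFrame(rows)


class TestStratifiedSplit:
    def test_default_study_80_20_per_class(self, feature_matrix):
        train, test = stratified_split(feature_matrix, 0.8, seed=3)
        assert len(train) == 4000 and len(test) == 1000
        for group, n in train["label"].value_counts().items():
            assert n == 800
        for group, n in test["label"].value_counts().items():
            assert n == 200
        assert set(train["id"]).isdisjoint(test["id"])
        assert set(train["id"]) | set(test["id"]) == set(feature_matrix["id"])

    def test_two_rows_per_class_split_one_one(self, rng):
        df = blobs_frame(rng, n_per_class=2)
        train, test = stratified_split(df, 0.5, seed=0)
        assert train["label"].value_counts().eq(1).all()
        assert test["label"].value_counts().eq(1).all()

    def test_seed_determinism(self, rng):
        df = blobs_frame(rng)
        t1, _ = stratified_split(df, 0.8, seed=5)
        t2, _ = stratified_split(df, 0.8, seed=5)
        t3, _ = stratified_split(df, 0.8, seed=6)
        assert list(t1["id"]) == list(t2["id"])
        assert list(t1["id"]) != list(t3["id"])
        assert t1["label"].value_counts().to_dict() == t3["label"].value_counts().to_dict()

    def test_grouped_policy_keeps_origin_families_together(self, feature_matrix):
        train, test = stratified_split(feature_matrix, 0.8, seed=3, policy="grouped")
        assert set(train["origin_id"]).isdisjoint(set(test["origin_id"]))
        assert len(train) == 4000 and len(test) == 1000

    def test_rowwise_policy_lets_families_straddle(self, feature_matrix):
        train, test = stratified_split(feature_matrix, 0.8, seed=3, policy="rowwise")
        assert not set(train["origin_id"]).isdisjoint(set(test["origin_id"]))

    def test_tiny_class_rejected(self, rng):
        df = blobs_frame(rng, n_per_class=2).iloc[:-1]
        with pytest.raises(ValueError):
            stratified_split(df, 0.5, seed=0)


class TestTrainSVM:
    def test_separable_clouds_reach_perfect_training_accuracy(self, rng):
        df = blobs_frame(rng, spread=0.3, sep=10.0)
        model = train_svm(df, "linear", SVMHyperparameters(C=100.0))
        report = evaluate(model, df)
        assert report.accuracy == 100.0

    def test_single_class_rejected(self, rng):
        df = blobs_frame(rng, n_classes=1)
        with pytest.raises(ValueError):
            train_svm(df, "linear")

    def test_nonfinite_features_rejected(self, rng):
        df = blobs_frame(rng)
        df.loc[0, "f1"] = np.nan
        with pytest.raises(ValueError):
            train_svm(df, "rbf")

    def test_duplicated_rows_leave_boundary_unchanged(self, rng):
        df = blobs_frame(rng)
        doubled = pd.concat([df, df], ignore_index=True)
        probe = rng.normal(0, 6, size=(50, 2))
        m1 = train_svm(df, "linear")
        m2 = train_svm(doubled, "linear")
        assert np.array_equal(m1.predict(probe), m2.predict(probe))


class TestDecisionScore:
    def test_hand_set_two_support_vectors_linear(self):
        # f(x) = 0.5*<x,(1,0)> - 0.5*<x,(0,1)> + 0.25 at x=(2,1): 1 - 0.5 + 0.25
        score = binary_decision_score(
            np.array([2.0, 1.0]),
            np.array([[1.0, 0.0], [0.0, 1.0]]),
            np.array([0.5, -0.5]),
            0.25,
            kernel="linear",
        )
        assert score == pytest.approx(0.75)

    def test_single_support_vector_scores_self_inner_product(self, rng):
        x1 = rng.normal(size=4)
        score = binary_decision_score(x1, x1[None, :], np.array([1.0]), 0.0, kernel="linear")
        assert score == pytest.approx(float(x1 @ x1))

    def test_rbf_kernel_at_its_support_vector_is_one(self, rng):
        sv = rng.normal(size=3)
        score = binary_decision_score(sv, sv[None, :], np.array([1.0]), 0.0, kernel="rbf", gamma=0.7)
        assert score == pytest.approx(1.0)

    @pytest.mark.parametrize("kernel", ["rbf", "polynomial", "linear"])
    def test_matches_fitted_ovo_decision_function(self, rng, kernel):
        df = blobs_frame(rng, n_classes=4, spread=2.0, sep=4.0)
        model = train_svm(df, kernel)
        x = df[["f1", "f2"]].to_numpy()[11]
        scores = decision_score(model, x)
        ref = model.svc.decision_function(model.scaler.transform(x[None, :]))[0]
        assert np.allclose(list(scores.values()), ref, atol=1e-9)
        assert len(scores) == 6  # one per unordered class pair


class TestEvaluate:
    def test_perfect_predictor_metrics(self, rng):
        df = blobs_frame(rng, spread=0.2, sep=10.0)
        model = train_svm(df, "rbf", SVMHyperparameters(C=100.0))
        report = evaluate(model, df)
        assert np.array_equal(np.diag(report.confusion), [40, 40, 40])
        assert report.accuracy == 100.0
        assert all(v == 100.0 for v in report.sensitivity.values())
        assert all(v == 100.0 for v in report.specificity.values())

    def test_constant_predictor_forced_metrics(self):
        classes = ("day0", "day5", "day10", "day15", "day20")
        cm = np.zeros((5, 5), dtype=int)
        cm[:, 0] = 40  # everything predicted day0 on a balanced test set
        sens, spec, acc = metrics_from_confusion(cm, classes)
        assert acc == pytest.approx(20.0)
        assert sens["day0"] == 100.0
        assert all(sens[c] == 0.0 for c in classes[1:])
        assert spec["day0"] == 0.0
        assert all(spec[c] == 100.0 for c in classes[1:])

    def test_hand_confusion_matrix_arithmetic(self):
        classes = ("a", "b", "c", "d", "e")
        cm = np.array(
            [
                [8, 1, 1, 0, 0],
                [0, 9, 0, 1, 0],
                [2, 0, 7, 0, 1],
                [0, 0, 0, 10, 0],
                [1, 0, 0, 0, 9],
            ]
        )
        sens, spec, acc = metrics_from_confusion(cm, classes)
        # hand arithmetic: trace 43 of 50; class a: TP 8/10, FP 3, TN 37
        assert acc == pytest.approx(86.0)
        assert sens["a"] == pytest.approx(80.0)
        assert spec["a"] == pytest.approx(37 / 40 * 100)
        assert sens["d"] == pytest.approx(100.0)
        assert spec["d"] == pytest.approx(39 / 40 * 100)

    def test_empty_test_class_flagged(self, rng):
        df = blobs_frame(rng)
        model = train_svm(df, "linear")
        subset = df[df["label"] != "c1"]
        report = evaluate(model, subset)
        assert report.undefined_sensitivity == ("c1",)
        assert np.isnan(report.sensitivity["c1"])

    def test_empty_partition_rejected(self, rng):
        df = blobs_frame(rng)
        model = train_svm(df, "linear")
        with pytest.raises(ValueError):
            evaluate(model, df.iloc[:0])


class TestRepeatedHoldout:
    def test_repeat_and_kernel_counts(self, rng):
        df = blobs_frame(rng)
        result = repeated_holdout(df, kernels=("rbf", "polynomial", "linear"), n_repeats=2, master_seed=1)
        assert result.n_reports == 6
        assert set(result.best_models) == {"rbf", "polynomial", "linear"}

    def test_single_repeat_best_is_only(self, rng):
        df = blobs_frame(rng)
        result = repeated_holdout(df, kernels=("linear",), n_repeats=1, master_seed=1)
        assert result.best_reports["linear"] is result.reports["linear"][0]

    def test_same_split_seeds_across_kernels(self, rng):
        df = blobs_frame(rng)
        result = repeated_holdout(df, kernels=("rbf", "linear"), n_repeats=3, master_seed=9)
        seeds_rbf = [r.split_seed for r in result.reports["rbf"]]
        seeds_lin = [r.split_seed for r in result.reports["linear"]]
        assert seeds_rbf == seeds_lin
        assert len(set(seeds_rbf)) == 3

    def test_metrics_consistency_of_all_reports(self, rng):
        df = blobs_frame(rng)
        result = repeated_holdout(df, kernels=("rbf",), n_repeats=3, master_seed=2)
        for report in result.reports["rbf"]:
            assert report.confusion.sum() == 24  # 20% of 120 rows
            recomputed = np.trace(report.confusion) / report.confusion.sum() * 100
            assert report.accuracy == recomputed

    def test_grouped_policy_no_leakage_advantage(self):
        """Rescaled copies of one trace straddle a row-wise split and let the
        model memorize families; keeping families together can only lower
        measured accuracy.  Amplitude-only templates make the effect stark:
        augmentation destroys the class signal, so only leakage remains."""
        design = StudyDesign(
            n_tissues_per_group=2, n_positions_per_tissue=2, n_replicates_per_position=2
        )
        base = default_templates(design)["day10"]
        templates = {
            label: ClassTemplate(
                frequencies=base.frequencies,
                dampings=base.dampings,
                component_amplitudes=base.component_amplitudes,
                onsets=base.onsets,
                amplitude_scale=1.0 + 0.3 * g,
                noise_sd=base.noise_sd,
            )
            for g, label in enumerate(design.group_labels)
        }
        accs = {"rowwise": [], "grouped": []}
        for seed in range(3):
            spectra = generate_dataset(design, templates, seed=seed)
            roi = preprocess_set(spectra, options=PreprocessOptions(normalize=False))
            table = extract_aa2_features(augment_set(roi))
            matrix = build_feature_matrix(table, mrmr_rank(table, k=10), 10)
            for policy in ("rowwise", "grouped"):
                result = repeated_holdout(
                    matrix, kernels=("rbf",), n_repeats=2, master_seed=seed, policy=policy
                )
                accs[policy].extend(r.accuracy for r in result.reports["rbf"])
        assert np.mean(accs["grouped"]) <= np.mean(accs["rowwise"])
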