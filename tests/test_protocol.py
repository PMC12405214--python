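"""Fold planning, augmentation, schedule semantics, metrics, patient rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from radfusion.fusionnet import FusionConfig
from radfusion.phantom import PhantomParams, generate_cohort, cohort_patients
from radfusion.protocol import (
    DataSplit,
    FoldMetrics,
    PhaseConfig,
    PlateauEarlyStop,
    TrainConfig,
    aggregate_folds,
    augment,
    compute_metrics,
    discordance_rate,
    make_fold_plan,
    run_nested_cv,
    strict_patient_accuracy,
    train_two_phase,
)
from radfusion.selection import LeakageError


def _patients(n_per_class):
    rows = [(f"P{i:03d}", "infection") for i in range(n_per_class)]
    rows += [(f"C{i:03d}", "control") for i in range(n_per_class)]
    return pd.DataFrame(rows, columns=["patient_id", "label"])


class TestFoldPlan:
    def test_104_patients_gives_balanced_outer_folds(self):
        plan = make_fold_plan(_patients(52), outer_k=5, seed=0)
        sizes = sorted(len(plan.test_patients(f)) for f in range(1, 6))
        assert sizes == [20, 21, 21, 21, 21]

    def test_partition_and_stratification(self):
        pts = _patients(10)
        plan = make_fold_plan(pts, outer_k=5, inner_k=3, seed=1)
        assert sorted(plan.outer_assignments) == sorted(pts["patient_id"])
        for f in range(1, 6):
            test = set(plan.test_patients(f))
            pool = set(plan.pool_patients(f))
            assert not test & pool
            inner = plan.inner_assignments[f]
            assert set(inner) == pool
            assert set(inner.values()) <= {1, 2, 3}
        # per-class fold sizes differ by <= 1
        lab = dict(zip(pts["patient_id"], pts["label"]))
        for cls in ("infection", "control"):
            per_fold = [sum(1 for p in plan.test_patients(f) if lab[p] == cls)
                        for f in range(1, 6)]
            assert max(per_fold) - min(per_fold) <= 1

    def test_deterministic_given_seed(self):
        a = make_fold_plan(_patients(10), seed=3)
        b = make_fold_plan(_patients(10), seed=3)
        assert a.outer_assignments == b.outer_assignments
        assert a.inner_assignments == b.inner_assignments

    def test_too_few_patients(self):
        with pytest.raises(ValueError):
            make_fold_plan(_patients(3), outer_k=5)


class TestAugment:
    def test_identity_draw_returns_input(self):
        rng = np.random.default_rng(0)
        patch = np.random.default_rng(1).random((32, 32))
        out = augment(patch, rng, p=0.0)
        assert np.array_equal(out, patch)

    def test_double_flip_is_involution(self):
        patch = np.random.default_rng(2).random((32, 32))
        # zero geometric ranges, p=1 -> both flips applied deterministically
        once = augment(patch, np.random.default_rng(0), rotation_deg=0,
                       zoom=0, translation=0, p=1.0)
        twice = augment(once, np.random.default_rng(0), rotation_deg=0,
                        zoom=0, translation=0, p=1.0)
        assert np.allclose(twice, patch)

    def test_seeded_stream_is_deterministic(self):
        patch = np.random.default_rng(3).random((32, 32))
        a = augment(patch, np.random.default_rng(42))
        b = augment(patch, np.random.default_rng(42))
        assert np.array_equal(a, b)
        assert a.shape == patch.shape


class TestScheduler:
    def test_strict_improvement_never_stops(self):
        s = PlateauEarlyStop(lr=1e-4, stop_patience=10)
        for epoch in range(50):
            lr, stop, best = s.update(1.0 / (epoch + 1))
            assert not stop and best and lr == 1e-4

    def test_constant_loss_stops_exactly_at_patience(self):
        s = PlateauEarlyStop(lr=1e-4, stop_patience=10, plateau_patience=5)
        stops = []
        for epoch in range(1, 12):
            _, stop, _ = s.update(1.0)
            stops.append(stop)
        # epoch 1 sets the best; stop triggers at epoch 11 = 1 + patience
        assert stops.index(True) == 10

    def test_plateau_halves_lr_down_to_floor(self):
        s = PlateauEarlyStop(lr=1e-4, factor=0.5, min_lr=1e-7,
                             plateau_patience=2, stop_patience=100)
        lrs = [s.update(1.0)[0] for _ in range(60)]
        assert lrs[0] == 1e-4
        # first reduction after 2 stalled epochs following the best epoch
        assert lrs[2] == 5e-5
        assert min(lrs) >= 1e-7
        assert lrs[-1] == 1e-7

    def test_phase_config_validation(self):
        with pytest.raises(ValueError):
            PhaseConfig(lr=1e-8, max_epochs=10, early_stop_patience=2,
                        min_lr=1e-7)


class TestMetrics:
    def test_perfect_predictions(self):
        m = compute_metrics(np.array([0.9, 0.9, 0.1, 0.1]),
                            np.array([1, 1, 0, 0]))
        assert m.accuracy == m.precision == m.recall == m.f1 == 100.0
        assert m.auc == 1.0

    def test_confusion_matrix_hand_example(self):
        # TP=3, FP=1, FN=2, TN=4
        probs = np.array([0.9, 0.9, 0.9, 0.1, 0.1, 0.9, 0.1, 0.1, 0.1, 0.1])
        labels = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0])
        m = compute_metrics(probs, labels)
        assert m.precision == pytest.approx(75.0)
        assert m.recall == pytest.approx(60.0)
        assert m.f1 == pytest.approx(200 * 0.75 * 0.6 / 1.35, abs=1e-6)
        assert m.accuracy == pytest.approx(70.0)

    def test_roc_extremes(self):
        labels = np.array([0, 1, 0, 1])
        assert compute_metrics(labels.astype(float), labels).auc == 1.0
        with np.errstate(all="ignore"):
            m = compute_metrics(np.full(4, 0.5), labels)
        assert m.auc == pytest.approx(0.5)

    def test_single_class_warns_with_nan_auc(self):
        with pytest.warns(RuntimeWarning):
            m = compute_metrics(np.array([0.9, 0.8]), np.array([1, 1]))
        assert np.isnan(m.auc)
        assert m.accuracy == 100.0


class TestAggregate:
    def _fm(self, fold, acc, roc=None, auc=0.5):
        roc = roc if roc is not None else np.array([[0, 0], [1, 1]], float)
        return FoldMetrics(fold, acc, acc, acc, acc, roc, auc)

    def test_identical_folds_zero_sd(self):
        agg = aggregate_folds([self._fm(1, 80.0), self._fm(2, 80.0)])
        assert (agg["table"]["sd"] == 0).all()
        assert np.allclose(agg["roc"]["tpr_mean"], agg["roc"]["fpr"])

    def test_mean_and_sample_sd_hand_example(self):
        agg = aggregate_folds([self._fm(1, 70.0), self._fm(2, 80.0)])
        row = agg["table"].set_index("metric").loc["accuracy"]
        assert row["mean"] == pytest.approx(75.0)
        assert row["sd"] == pytest.approx(np.sqrt(50), abs=1e-9)  # 7.071

    def test_needs_two_folds(self):
        with pytest.raises(ValueError):
            aggregate_folds([self._fm(1, 70.0)])


class TestStrictPatientRule:
    def test_exhaustive_truth_table(self):
        pairs = [(0, 0), (0, 1), (1, 0), (1, 1)]
        inf_correct = sum(
            strict_patient_accuracy({"P": pr}, {"P": "infection"})[0]["infection"]
            for pr in pairs
        )
        ctl_correct = sum(
            strict_patient_accuracy({"P": pr}, {"P": "control"})[0]["control"]
            for pr in pairs
        )
        assert inf_correct == 3  # any positive flags infection
        assert ctl_correct == 1  # only (0,0) clears a control

    def test_wrong_cardinality_rejected(self):
        with pytest.raises(ValueError):
            strict_patient_accuracy({"P": (1,)}, {"P": "control"})

    def test_discordance_counting(self):
        preds = {f"P{i}": (1, 0) if i < 3 else (1, 1) for i in range(10)}
        _, decisions = strict_patient_accuracy(
            preds, {p: "infection" for p in preds})
        mean, sd = discordance_rate([decisions])
        assert mean == pytest.approx(30.0)
        assert sd == 0.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.tuples(st.booleans(), st.integers(0, 1),
                              st.integers(0, 1)), min_size=4, max_size=30))
    def test_rule_dominance_over_roi_rates(self, rows):
        """Strict infection accuracy >= ROI-level recall; strict control
        accuracy <= ROI-level specificity, on any prediction set."""
        preds, labels = {}, {}
        roi_y, roi_p = [], []
        for i, (is_inf, a, b) in enumerate(rows):
            pid = f"P{i}"
            labels[pid] = "infection" if is_inf else "control"
            preds[pid] = (a, b)
            roi_y += [int(is_inf)] * 2
            roi_p += [a, b]
        acc, _ = strict_patient_accuracy(preds, labels)
        roi_y, roi_p = np.array(roi_y), np.array(roi_p)
        if "infection" in acc:
            recall = (roi_p[roi_y == 1] == 1).mean()
            assert acc["infection"] >= recall - 1e-12
        if "control" in acc:
            specificity = (roi_p[roi_y == 0] == 0).mean()
            assert acc["control"] <= specificity + 1e-12


MICRO_CFG = FusionConfig(
    backbone="densenet201-style", input_size=8, stem_width=4,
    stage_widths=(8,), backbone_channels=8, aspp_filters=4,
    context_filters=4, compress_filters=4, radiomics_widths=(4, 8),
    head_width=4,
)

MICRO_TRAIN = TrainConfig(
    phase1=PhaseConfig(lr=1e-3, max_epochs=2, early_stop_patience=1),
    phase2=PhaseConfig(lr=1e-4, max_epochs=1, early_stop_patience=1,
                       freeze_fraction=0.7),
    batch_size=8, seed=0,
)


class TestTrainTwoPhase:
    def _split(self, pids, seed=0):
        rng = np.random.default_rng(seed)
        n = 2 * len(pids)
        y = np.tile([0, 1], len(pids))
        return DataSplit(
            images=rng.random((n, 8, 8, 3)),
            radiomics=rng.random((n, 50)),
            onehot=np.eye(2)[y], labels=y,
            patient_ids=tuple(p for p in pids for _ in range(2)),
            hemispheres=tuple(h for _ in pids for h in ("left", "right")),
        )

    def test_patient_overlap_rejected(self):
        from radfusion.fusionnet import build_fusion_model

        m = build_fusion_model(MICRO_CFG, seed=0)
        with pytest.raises(LeakageError):
            train_two_phase(m, self._split(["A", "B"]), self._split(["B", "C"]),
                            MICRO_TRAIN)

    def test_history_records_phases_and_lr_floor(self):
        from radfusion.fusionnet import build_fusion_model

        m = build_fusion_model(MICRO_CFG, seed=0)
        m, hist = train_two_phase(m, self._split(["A", "B"]),
                                  self._split(["C", "D"], seed=1), MICRO_TRAIN)
        assert set(hist["phase"]) == {"phase1", "phase2"}
        assert (hist["lr"] >= 1e-7).all()
        assert {"train_loss", "val_loss", "val_acc"} <= set(hist.columns)


@pytest.fixture(scope="module")
def result():
    cohort = generate_cohort(PhantomParams(n_patients_per_class=6, seed=2))
    return run_nested_cv(cohort, "ventricle", "fusion",
                         model_config=MICRO_CFG, train_config=MICRO_TRAIN)


class TestRunNestedCV:
    def test_bookkeeping_counts(self, result):
        assert len(result["fold_metrics"]) == 5
        assert len(result["selections"]) == 5
        assert all(len(s.selected) == 50 for s in result["selections"])
        assert result["selection_frequency"]["frequency"].sum() == 250

    def test_every_patient_tested_once(self, result):
        tested = [d.patient_id for decisions in result["fold_decisions"]
                  for d in decisions]
        assert sorted(tested) == sorted(set(tested))
        assert len(tested) == 12

    def test_fold_metrics_in_range(self, result):
        for m in result["fold_metrics"]:
            for v in (m.accuracy, m.precision, m.recall, m.f1):
                assert 0.0 <= v <= 100.0

    def test_scaler_from_training_only(self, result):
        for sel in result["selections"]:
            assert sel.scaler_mean is not None
            assert sel.scaler_sd.shape == (50,)
            assert (sel.scaler_sd > 0).all()
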