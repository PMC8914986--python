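"""Dice, boundary errors, pixel confusion metrics and run aggregation."""
from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from octlayers import (
    EvalConfig,
    PerturbationSpec,
    PerturbedOracleBackend,
    aggregate_runs,
    boundary_errors,
    confusion_metrics,
    dice,
    dice_report,
    evaluate_report,
    generate_phantom,
    boundaries_to_classmap,
)
from octlayers.phantom import BoundarySet
from conftest import oracle_roundtrip


class TestDice:
    def test_identical_masks_score_100(self):
        m = np.zeros((6, 6), dtype=bool)
        m[2:4, 1:5] = True
        assert dice(m, m) == 100.0

    def test_disjoint_masks_score_0(self):
        a = np.zeros((6, 6), dtype=bool)
        b = np.zeros((6, 6), dtype=bool)
        a[0] = True
        b[5] = True
        assert dice(a, b) == 0.0

    def test_half_overlap_formula(self):
        a = np.zeros((10, 20), dtype=bool)
        b = np.zeros((10, 20), dtype=bool)
        a.flat[:100] = True  # 100 px
        b.flat[50:150] = True  # 100 px, overlap 50 px
        assert dice(a, b) == 50.0  # 2*50 / 200

    def test_both_empty_is_perfect_absence(self):
        empty = np.zeros((4, 4), dtype=bool)
        assert dice(empty, empty) == 100.0

    def test_symmetry_and_self_identity(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a = rng.random((8, 8)) < 0.4
            b = rng.random((8, 8)) < 0.4
            assert dice(a, b) == dice(b, a)
            assert dice(a, a) == 100.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice(np.ones((3, 3), bool), np.ones((3, 4), bool))


class TestBoundaryErrors:
    def _flat_bounds(self, rows, width=1534):
        return BoundarySet("choroid3", np.vstack([np.full(width, float(r)) for r in rows]))

    def test_identical_traces_give_zero_errors(self):
        gt = self._flat_bounds([10, 20, 30])
        rep = boundary_errors(gt, gt, EvalConfig())
        assert rep.mean_signed == 0.0 and rep.mean_absolute == 0.0
        for be in rep.per_boundary.values():
            assert be.signed == 0.0 and be.absolute == 0.0

    def test_constant_shift_propagates(self):
        gt = self._flat_bounds([10, 20, 30])
        pred = self._flat_bounds([12, 22, 32])
        rep = boundary_errors(pred, gt, EvalConfig())
        assert rep.mean_signed == 2.0 and rep.mean_absolute == 2.0

    def test_default_margins_evaluate_1134_columns(self):
        gt = self._flat_bounds([10, 20, 30])
        rep = boundary_errors(gt, gt, EvalConfig())
        assert rep.evaluated_columns == 1134  # 1534 - 100 - 300
        assert all(be.n_columns == 1134 for be in rep.per_boundary.values())

    def test_undefined_columns_excluded_with_counts(self):
        gt = self._flat_bounds([10, 20, 30])
        pred = self._flat_bounds([10, 20, 30])
        pred.traces[1, 100:150] = np.nan
        rep = boundary_errors(pred, gt, EvalConfig())
        assert rep.per_boundary["RPE"].n_columns == 1134 - 50

    def test_signed_magnitude_bounded_by_absolute(self):
        rng = np.random.default_rng(11)
        gt = self._flat_bounds([10, 20, 30], width=600)
        pred = BoundarySet("choroid3", gt.traces + rng.normal(0, 2, gt.traces.shape))
        rep = boundary_errors(pred, gt, EvalConfig(exclude_left=40, exclude_right=120))
        for be in rep.per_boundary.values():
            assert abs(be.signed) <= be.absolute + 1e-12

    def test_absolute_error_translation_equivariant(self):
        rng = np.random.default_rng(12)
        gt = self._flat_bounds([10, 20, 30], width=600)
        pred = BoundarySet("choroid3", gt.traces + rng.normal(0, 1, gt.traces.shape))
        cfg = EvalConfig(exclude_left=40, exclude_right=120)
        base = boundary_errors(pred, gt, cfg)
        moved = boundary_errors(
            BoundarySet("choroid3", pred.traces + 7.0),
            BoundarySet("choroid3", gt.traces + 7.0),
            cfg,
        )
        assert moved.mean_absolute == pytest.approx(base.mean_absolute)

    def test_no_evaluable_columns_rejected(self):
        gt = self._flat_bounds([10, 20, 30])
        pred = BoundarySet("choroid3", np.full_like(gt.traces, np.nan))
        with pytest.raises(ValueError):
            boundary_errors(pred, gt, EvalConfig())

    def test_profile_mismatch_rejected(self):
        gt = self._flat_bounds([10, 20, 30])
        other = BoundarySet("retinal7", np.vstack([np.full(1534, 10.0 + k) for k in range(7)]))
        with pytest.raises(ValueError):
            boundary_errors(other, gt, EvalConfig())


class TestConfusionMetrics:
    def test_perfect_prediction_scores_100_everywhere(self, small_phantom, small_eval_config):
        _, _, labels = small_phantom
        rep = confusion_metrics(labels, labels, small_eval_config, "retinal7")
        for m in rep.per_class.values():
            assert m.accuracy == 100.0 and m.recall == 100.0
            assert m.precision == 100.0 and m.specificity == 100.0

    def test_all_background_prediction_has_zero_recall(self, small_phantom, small_eval_config):
        _, _, labels = small_phantom
        rep = confusion_metrics(np.zeros_like(labels), labels, small_eval_config, "retinal7")
        for m in rep.per_class.values():
            assert m.recall == 0.0

    def test_hand_counted_two_by_two_example(self):
        gt = np.array([[1, 0], [0, 0]])
        pred = np.array([[1, 1], [0, 0]])
        rep = confusion_metrics(pred, gt, None, "retinal7")
        m = rep.per_class["ILM-NFL"]
        assert (m.tp, m.fp, m.fn, m.tn) == (1, 1, 0, 2)
        assert m.precision == 50.0
        assert m.recall == 100.0
        assert m.accuracy == 75.0
        assert m.specificity == pytest.approx(200 / 3)

    def test_confusion_totals_conserved(self, small_phantom, small_eval_config):
        _, _, labels = small_phantom
        noisy = labels.copy()
        noisy[labels == 3] = 4
        rep = confusion_metrics(noisy, labels, small_eval_config, "retinal7")
        n = labels.shape[0] * small_eval_config.n_columns(labels.shape[1])
        for m in rep.per_class.values():
            assert m.tp + m.fp + m.fn + m.tn == n


class TestAggregateRuns:
    def test_closed_form_example(self):
        agg = aggregate_runs([1, 2, 3, 4])
        assert agg.mean == 2.5
        assert agg.sd == pytest.approx(1.2910, abs=1e-4)
        assert agg.n == 4

    def test_constant_runs_have_zero_spread(self):
        agg = aggregate_runs([5, 5, 5, 5])
        assert agg.mean == 5.0 and agg.sd == 0.0

    def test_permutation_invariance(self):
        a = aggregate_runs([3.0, 1.0, 4.0, 1.5])
        b = aggregate_runs([1.5, 4.0, 1.0, 3.0])
        assert a == b

    def test_single_run_rejected(self):
        with pytest.raises(ValueError):
            aggregate_runs([1.0])


class TestEvaluateReport:
    def test_oracle_pipeline_is_perfect(self, small_phantom, small_eval_config):
        bscan, bounds, labels = small_phantom
        fused, pred_bounds = oracle_roundtrip(bscan, labels, "retinal7", 64)
        report = evaluate_report(
            {"img0": (fused.labels, pred_bounds)},
            {"img0": (labels[:64], bounds)},
            "retinal7",
            small_eval_config,
        )
        ev = report.per_image["img0"]
        assert ev.dice.overall == 100.0
        assert ev.boundary.mean_absolute <= 0.5

    def test_id_mismatch_lists_offenders(self, small_phantom, small_eval_config):
        _, bounds, labels = small_phantom
        with pytest.raises(ValueError, match="img1"):
            evaluate_report(
                {"img0": (labels, bounds)},
                {"img1": (labels, bounds)},
                "retinal7",
                small_eval_config,
            )

    def test_vertical_shift_appears_in_signed_error(self, small_spec, small_eval_config):
        bscan, bounds = generate_phantom(replace(small_spec, integer_traces=True))
        labels = boundaries_to_classmap(bounds, small_spec.height)
        backend = PerturbedOracleBackend(
            "retinal7", PerturbationSpec(vertical_shift=2, seed=1)
        )
        _, pred_bounds = oracle_roundtrip(bscan, labels, "retinal7", 64, backend=backend)
        rep = boundary_errors(pred_bounds, bounds, small_eval_config)
        assert rep.mean_signed == pytest.approx(2.0, abs=0.5)

    def test_absolute_error_increases_with_shift(self, small_spec, small_eval_config):
        bscan, bounds = generate_phantom(small_spec)
        labels = boundaries_to_classmap(bounds, small_spec.height)
        maes = []
        for shift in range(6):
            backend = PerturbedOracleBackend(
                "retinal7", PerturbationSpec(vertical_shift=shift, seed=1)
            )
            _, pred = oracle_roundtrip(bscan, labels, "retinal7", 64, backend=backend)
            maes.append(boundary_errors(pred, bounds, small_eval_config).mean_absolute)
        assert all(b > a for a, b in zip(maes, maes[1:]))

    def test_dilation_degrades_dice_monotonically(self, small_phantom, small_eval_config):
        bscan, _, labels = small_phantom
        scores = []
        for dil in (0, 1, 3):
            backend = PerturbedOracleBackend(
                "retinal7", PerturbationSpec(dilation=dil, seed=1)
            )
            fused, _ = oracle_roundtrip(bscan, labels, "retinal7", 64, backend=backend)
            scores.append(
                dice_report(fused.labels, labels[:64], "retinal7", small_eval_config).per_layer_mean
            )
        assert scores[0] == 100.0
        assert scores[0] > scores[1] > scores[2]
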