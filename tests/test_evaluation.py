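import math
from fractions import Fraction

import numpy as np
import pytest

from oomil import (
    ConfusionMatrix,
    OrdinalCutpoints,
    build_network,
    evaluate,
    kid_stats,
    metrics_from_confusion,
    predict_class,
    render_selection,
)
from oomil.bag_builder import Bag, Instance
from oomil.trainer import SelectionRecord

CUTS = OrdinalCutpoints.from_boundaries(0.5, 1.5)


class TestPredictClass:
    @pytest.mark.parametrize("score, expected", [(-2.0, 0), (0.49, 0), (0.5, 1), (1.0, 1), (1.5, 2), (9.0, 2)])
    def test_scalar_thresholding(self, score, expected):
        assert predict_class(score, CUTS) == expected

    def test_softmax_argmax_with_low_class_ties(self):
        assert predict_class(np.array([0.2, 0.3, 0.5])) == 2
        assert predict_class(np.array([0.4, 0.4, 0.2])) == 0  # tie -> lower class

    def test_monotone_in_score(self):
        scores = np.linspace(-3, 3, 101)
        preds = predict_class(scores, CUTS)
        assert (np.diff(preds) >= 0).all()

    def test_scalar_without_cutpoints_rejected(self):
        with pytest.raises(ValueError):
            predict_class(0.7)


class TestMetricOracle:
    def test_perfect_predictions_give_unit_metrics(self):
        cm = ConfusionMatrix(np.diag([2, 2, 2]))
        rep = metrics_from_confusion(cm)
        assert rep.accuracy == 1.0
        assert rep.per_class_accuracy == [1.0, 1.0, 1.0]
        for v in (rep.sensitivity, rep.specificity, rep.precision, rep.f1):
            assert v == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_macro_metrics_to_1e12(self):
        """Independent textbook computation with exact rationals."""
        cm = ConfusionMatrix(np.array([[5, 3, 2], [1, 6, 3], [0, 2, 8]]))
        rep = metrics_from_confusion(cm, mode="macro_ovr")
        assert rep.accuracy == pytest.approx(19 / 30, abs=1e-12)
        assert rep.per_class_accuracy == pytest.approx([0.5, 0.6, 0.8], abs=1e-12)
        # one-vs-rest tables built by hand from the matrix
        prec = (Fraction(5, 6) + Fraction(6, 11) + Fraction(8, 13)) / 3
        sens = (Fraction(5, 10) + Fraction(6, 10) + Fraction(8, 10)) / 3
        spec = (Fraction(19, 20) + Fraction(15, 20) + Fraction(15, 20)) / 3
        assert rep.precision == pytest.approx(float(prec), abs=1e-12)
        assert rep.sensitivity == pytest.approx(float(sens), abs=1e-12)
        assert rep.specificity == pytest.approx(float(spec), abs=1e-12)
        f1 = 2 * prec * sens / (prec + sens)
        assert rep.f1 == pytest.approx(float(f1), abs=1e-12)

    def test_disease_binary_collapse(self):
        cm = ConfusionMatrix(np.array([[5, 3, 2], [1, 6, 3], [0, 2, 8]]))
        rep = metrics_from_confusion(cm, mode="disease_binary")
        # diseased = classes 1+2: TP 19, FN 1, FP 5, TN 5
        assert rep.sensitivity == pytest.approx(19 / 20, abs=1e-12)
        assert rep.specificity == pytest.approx(5 / 10, abs=1e-12)
        assert rep.precision == pytest.approx(19 / 24, abs=1e-12)

    def test_macro_invariant_under_class_relabelling(self):
        cm = np.array([[5, 3, 2], [1, 6, 3], [0, 2, 8]])
        base = metrics_from_confusion(ConfusionMatrix(cm))
        perm = [2, 0, 1]
        permuted = cm[np.ix_(perm, perm)]
        rep = metrics_from_confusion(ConfusionMatrix(permuted))
        assert rep.sensitivity == pytest.approx(base.sensitivity, abs=1e-12)
        assert rep.specificity == pytest.approx(base.specificity, abs=1e-12)
        assert rep.precision == pytest.approx(base.precision, abs=1e-12)
        assert rep.accuracy == pytest.approx(base.accuracy, abs=1e-12)

    def test_empty_class_excluded_from_macro_mean(self):
        cm = ConfusionMatrix(np.array([[4, 1, 0], [2, 3, 0], [0, 0, 0]]))
        rep = metrics_from_confusion(cm)
        assert math.isnan(rep.per_class_accuracy[2])
        # macro sensitivity averages only the two populated classes
        assert rep.sensitivity == pytest.approx((4 / 5 + 3 / 5) / 2, abs=1e-12)

    def test_matrix_validation(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(np.array([[1, -1, 0], [0, 0, 0], [0, 0, 0]]))
        with pytest.raises(ValueError):
            metrics_from_confusion(ConfusionMatrix(np.zeros((3, 3))))


class TestEvaluate:
    def test_confusion_total_equals_test_size(self, tiny_spec):
        net = build_network(tiny_spec, seed=0)
        rng = np.random.default_rng(0)
        test = [(rng.random((16, 16), dtype=np.float32), int(rng.integers(3))) for _ in range(12)]
        cm, rep = evaluate(net, CUTS, test)
        assert cm.total == 12
        assert 0.0 <= rep.accuracy <= 1.0

    def test_empty_test_set_rejected(self, tiny_spec):
        with pytest.raises(ValueError):
            evaluate(build_network(tiny_spec, seed=0), CUTS, [])


class TestKidStats:
    def _bags(self):
        def bag(bid, label, hidden):
            insts = [
                Instance(pixels=np.zeros((4, 4), np.float32), grid_row=0, grid_col=i, hidden_label=h)
                for i, h in enumerate(hidden)
            ]
            return Bag(bag_id=bid, instances=insts, label=label)

        return [bag("n", 0, [0] * 4), bag("p1", 1, [1, 0, 0, 0]), bag("p2", 2, [2, 2, 0, 0])]

    def test_all_correct_selection_has_unit_precision(self):
        bags = self._bags()
        history = [
            SelectionRecord(0, "p1", [0], [0.1], n_true_positive=1),
            SelectionRecord(0, "p2", [0, 1], [0.1, 0.2], n_true_positive=2),
        ]
        stats = kid_stats(history, bags)
        assert stats[0]["precision"] == 1.0
        assert stats[0]["mean_s"] == 1.5

    def test_normal_bags_are_ignored(self):
        bags = self._bags()
        history = [
            SelectionRecord(0, "n", [0, 1], [0.1, 0.2], n_true_positive=2),
            SelectionRecord(0, "p1", [1], [0.1], n_true_positive=0),
        ]
        stats = kid_stats(history, bags)
        assert stats[0]["n_bags"] == 1
        assert stats[0]["precision"] == 0.0

    def test_random_selection_matches_positive_rate(self):
        """Monte-Carlo: random k-subsets of a 10%-positive bag select
        positives at ~10% precision."""
        rng = np.random.default_rng(0)
        hidden = [1] * 2 + [0] * 18  # 10% positive
        insts = [
            Instance(pixels=np.zeros((2, 2), np.float32), grid_row=0, grid_col=i, hidden_label=h)
            for i, h in enumerate(hidden)
        ]
        bag = Bag(bag_id="mc", instances=insts, label=1)
        history = []
        for t in range(3000):
            sel = rng.choice(20, size=2, replace=False)
            s = sum(hidden[i] for i in sel)
            history.append(SelectionRecord(0, "mc", list(map(int, sel)), [0.0, 0.0], n_true_positive=s))
        stats = kid_stats(history, [bag])
        assert stats[0]["precision"] == pytest.approx(0.1, abs=0.02)

    def test_missing_hidden_labels_rejected(self):
        bags = self._bags()
        history = [SelectionRecord(0, "p1", [0], [0.1], n_true_positive=None)]
        with pytest.raises(ValueError):
            kid_stats(history, bags)


class TestRenderSelection:
    def _bag(self, hidden):
        insts = [
            Instance(
                pixels=np.full((8, 8), 0.5, np.float32),
                grid_row=0,
                grid_col=i,
                hidden_label=h,
            )
            for i, h in enumerate(hidden)
        ]
        return Bag(bag_id="r", instances=insts, label=1)

    def test_outline_counts_and_colors(self):
        bag = self._bag([1, 0, 0, 1])
        rec = SelectionRecord(0, "r", [0, 1], [0.1, 0.2], n_true_positive=1)
        img = render_selection(bag, rec, tile_side=16, grid_cols=4)
        assert img.shape == (16, 64, 3)
        red = (img[0, :, 0] == 255) & (img[0, :, 2] < 100)
        blue = (img[0, :, 2] == 255) & (img[0, :, 0] < 100)
        assert red.sum() == 16  # instance 0: correct -> red outline
        assert blue.sum() == 16  # instance 1: wrong -> blue outline

    def test_neutral_color_without_hidden_labels(self):
        bag = self._bag([None, None])
        rec = SelectionRecord(0, "r", [0], [0.1])
        img = render_selection(bag, rec, tile_side=16, grid_cols=2)
        top_left = img[0, 0]
        assert top_left[0] == 255 and top_left[2] < 100  # yellow-ish
        assert top_left[1] > 200

    def test_mismatched_record_rejected(self):
        bag = self._bag([0, 0])
        rec = SelectionRecord(0, "r", [5], [0.1])
        with pytest.raises(ValueError):
            render_selection(bag, rec)

    def test_written_to_disk(self, tmp_path):
        import imageio.v3 as iio

        bag = self._bag([1, 0])
        rec = SelectionRecord(0, "r", [0], [0.1], n_true_positive=1)
        path = tmp_path / "sel.png"
        render_selection(bag, rec, path=path, tile_side=8, grid_cols=2)
        assert iio.imread(path).shape == (8, 16, 3)
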