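"""Evaluation metrics against hand calculations and brute-force oracles."""

import numpy as np
import pytest

from munet.metrics import (
    ConfusionCounts,
    UndefinedMetricError,
    confusion,
    dsc_iou,
    evaluate_case,
    extract_boundary,
    hausdorff95,
    kappa,
    rate_metrics,
)


# -- independent brute-force oracles ---------------------------------------


def brute_confusion(pred, truth):
    tp = tn = fp = fn = 0
    for p, t in zip(pred.ravel(), truth.ravel()):
        if p and t:
            tp += 1
        elif p and not t:
            fp += 1
        elif not p and t:
            fn += 1
        else:
            tn += 1
    return tp, tn, fp, fn


def brute_kappa(tp, tn, fp, fn):
    n = tp + tn + fp + fn
    po = (tp + tn) / n
    pe = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / n**2
    return (po - pe) / (1 - pe)


def brute_hausdorff95(A, B):
    dmat = np.sqrt(((A[:, None, :] - B[None, :, :]) ** 2).sum(-1))
    h_ab = np.percentile(dmat.min(axis=1), 95)
    h_ba = np.percentile(dmat.min(axis=0), 95)
    return max(h_ab, h_ba)


class TestConfusionAndKappa:
    def test_perfect_agreement(self, rng):
        m = rng.integers(0, 2, size=(5, 5)).astype(bool)
        c = confusion(m, m)
        assert c.fp == 0 and c.fn == 0
        assert kappa(c) == pytest.approx(1.0)

    def test_total_disagreement(self):
        c = confusion(np.ones((3, 3), bool), np.zeros((3, 3), bool))
        assert (c.fp, c.tp, c.tn, c.fn) == (9, 0, 0, 0)

    def test_counts_match_per_pixel_tally(self, rng):
        pred = rng.integers(0, 2, size=(10, 10)).astype(bool)
        truth = rng.integers(0, 2, size=(10, 10)).astype(bool)
        c = confusion(pred, truth)
        assert (c.tp, c.tn, c.fp, c.fn) == brute_confusion(pred, truth)

    def test_printed_style_confusion_example(self):
        c = ConfusionCounts(tp=40, fn=10, fp=20, tn=30)
        assert c.p_o == pytest.approx(0.7)
        assert c.p_e == pytest.approx(0.5)
        assert kappa(c) == pytest.approx(0.4)

    def test_chance_level_is_zero(self):
        # independent raters: counts proportional to marginal products
        c = ConfusionCounts(tp=12, fn=28, fp=18, tn=42)  # pred+ 0.3, truth+ 0.4
        assert kappa(c) == pytest.approx(0.0, abs=1e-12)

    def test_both_constant_raises(self):
        with pytest.raises(UndefinedMetricError):
            kappa(ConfusionCounts(tp=9, fn=0, fp=0, tn=0))

    def test_label_swap_invariance(self, rng):
        pred = rng.integers(0, 2, size=(8, 8)).astype(bool)
        truth = rng.integers(0, 2, size=(8, 8)).astype(bool)
        assert kappa(confusion(pred, truth)) == pytest.approx(
            kappa(confusion(~pred, ~truth))
        )


class TestRates:
    def test_direct_substitution(self):
        r = rate_metrics(ConfusionCounts(tp=30, fn=10, tn=45, fp=15))
        assert r.sensitivity == pytest.approx(0.75)
        assert r.specificity == pytest.approx(0.75)
        assert r.precision == pytest.approx(2 / 3)
        assert r.accuracy == pytest.approx(0.75)
        assert r.balanced_accuracy == pytest.approx(0.75)

    def test_perfect_prediction_all_ones(self):
        r = rate_metrics(ConfusionCounts(tp=5, fn=0, tn=5, fp=0))
        assert all(
            v == 1.0
            for v in (r.sensitivity, r.precision, r.specificity, r.accuracy,
                      r.balanced_accuracy)
        )

    def test_degenerate_denominator_reported_undefined(self):
        r = rate_metrics(ConfusionCounts(tp=0, fn=0, tn=8, fp=2))
        assert r.sensitivity is None
        assert r.balanced_accuracy is None
        assert r.specificity == pytest.approx(0.8)


class TestDscIou:
    def test_identical_nonempty(self, rng):
        m = rng.integers(0, 2, size=(6, 6)).astype(bool)
        m[0, 0] = True
        assert dsc_iou(m, m) == (1.0, 1.0)

    def test_direct_counting_and_identity(self):
        pred = np.zeros(10, bool)
        truth = np.zeros(10, bool)
        pred[:4] = True
        truth[1:7] = True  # |X|=4, |Y|=6, |∩|=3
        dsc, iou = dsc_iou(pred, truth)
        assert dsc == pytest.approx(0.6)
        assert iou == pytest.approx(3 / 7)
        assert dsc == pytest.approx(2 * iou / (1 + iou))

    def test_disjoint_and_both_empty(self):
        a = np.zeros((3, 3), bool)
        b = np.zeros((3, 3), bool)
        assert dsc_iou(a, b) == (1.0, 1.0)
        a2 = a.copy()
        a2[0, 0] = True
        b2 = b.copy()
        b2[2, 2] = True
        assert dsc_iou(a2, b2) == (0.0, 0.0)


class TestBoundary:
    def test_single_pixel(self):
        m = np.zeros((3, 3), bool)
        m[1, 1] = True
        assert extract_boundary(m).tolist() == [[1, 1]]

    def test_solid_square_perimeter(self):
        m = np.zeros((6, 6), bool)
        m[1:5, 1:5] = True
        pts = set(map(tuple, extract_boundary(m)))
        expected = {
            (i, j)
            for i in range(1, 5)
            for j in range(1, 5)
            if i in (1, 4) or j in (1, 4)
        }
        assert pts == expected and len(expected) == 12

    def test_thin_line_is_all_boundary(self):
        m = np.zeros((5, 5), bool)
        m[2, :] = True
        assert len(extract_boundary(m)) == 5

    def test_degenerate_masks_raise(self):
        with pytest.raises(ValueError):
            extract_boundary(np.zeros((3, 3), bool))
        with pytest.raises(ValueError):
            extract_boundary(np.ones((3, 3), bool))


class TestHausdorff95:
    def test_identical_sets_zero(self, rng):
        A = rng.integers(0, 10, size=(12, 2))
        assert hausdorff95(A, A) == 0.0

    def test_single_point_pair(self):
        assert hausdorff95(np.array([[0, 0]]), np.array([[3, 4]])) == pytest.approx(5.0)

    def test_symmetry_and_bound_by_exact_hausdorff(self, rng):
        for _ in range(20):
            A = rng.uniform(0, 20, size=(rng.integers(2, 40), 2))
            B = rng.uniform(0, 20, size=(rng.integers(2, 40), 2))
            h = hausdorff95(A, B)
            assert h == pytest.approx(hausdorff95(B, A))
            dmat = np.sqrt(((A[:, None] - B[None]) ** 2).sum(-1))
            exact = max(dmat.min(axis=1).max(), dmat.min(axis=0).max())
            assert h <= exact + 1e-12

    def test_matches_brute_force(self, rng):
        for _ in range(30):
            A = rng.uniform(0, 15, size=(rng.integers(1, 40), 2))
            B = rng.uniform(0, 15, size=(rng.integers(1, 40), 2))
            assert hausdorff95(A, B) == pytest.approx(
                brute_hausdorff95(A, B), abs=1e-9
            )

    def test_empty_set_raises(self):
        with pytest.raises(ValueError):
            hausdorff95(np.empty((0, 2)), np.array([[0, 0]]))


class TestEvaluateCase:
    @staticmethod
    def _labels(shape=(16, 16)):
        lab = np.zeros(shape, dtype=np.int16)
        lab[4:12, 4:12] = 2
        lab[6:10, 6:10] = 4
        lab[7:9, 7:9] = 1
        return lab

    def test_self_evaluation_perfect(self):
        lab = self._labels()
        reports = evaluate_case(lab, lab)
        for rep in reports.values():
            assert rep.dsc == 1.0 and rep.iou == 1.0
            assert rep.hausdorff95 == 0.0
            assert rep.kappa == pytest.approx(1.0)

    def test_one_pixel_shift_hausdorff(self):
        lab = self._labels()
        shifted = np.zeros_like(lab)
        shifted[:, 1:] = lab[:, :-1]
        rep = evaluate_case(shifted, lab)["WT"]
        assert rep.hausdorff95 == pytest.approx(1.0)

    def test_unknown_label_rejected(self):
        lab = self._labels()
        bad = lab.copy()
        bad[0, 0] = 3
        with pytest.raises(ValueError):
            evaluate_case(bad, lab)

    def test_statelessness(self):
        lab = self._labels()
        pred = np.roll(lab, 1, axis=0)
        r1 = evaluate_case(pred, lab)
        r2 = evaluate_case(pred, lab)
        assert {k: v.to_dict() for k, v in r1.items()} == {
            k: v.to_dict() for k, v in r2.items()
        }


def test_oracle_equivalence_on_random_masks(rng):
    """Every metric agrees with independent brute-force implementations."""
    for _ in range(40):
        pred = rng.integers(0, 2, size=(12, 12)).astype(bool)
        truth = rng.integers(0, 2, size=(12, 12)).astype(bool)
        c = confusion(pred, truth)
        tp, tn, fp, fn = brute_confusion(pred, truth)
        assert (c.tp, c.tn, c.fp, c.fn) == (tp, tn, fp, fn)
        if not (tp + fp == 0 or tp + fn == 0 or tn + fp == 0 or tn + fn == 0):
            assert kappa(c) == pytest.approx(brute_kappa(tp, tn, fp, fn), abs=1e-9)
        dsc, iou = dsc_iou(pred, truth)
        inter = (pred & truth).sum()
        if pred.sum() + truth.sum():
            assert dsc == pytest.approx(2 * inter / (pred.sum() + truth.sum()), abs=1e-9)
            assert iou == pytest.approx(inter / (pred | truth).sum(), abs=1e-9)
        if pred.any() and not pred.all() and truth.any() and not truth.all():
            A = extract_boundary(pred)
            B = extract_boundary(truth)
            assert hausdorff95(A, B) == pytest.approx(
                brute_hausdorff95(A.astype(float), B.astype(float)), abs=1e-9
            )
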