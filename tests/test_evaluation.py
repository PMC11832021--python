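import numpy as np
import pytest
from sklearn.metrics import f1_score, matthews_corrcoef

from poresip import evaluation as ev
from poresip.evaluation import (
    ConfusionCounts,
    CvConfig,
    FdrPoint,
    balance_classes,
    confusion,
    crossvalidate,
    cutoff_for_fdr,
    error_response_curve,
    f1,
    fdr_curve,
    make_folds,
    mcc,
)
from poresip.glm_model import ModelConfig, Prediction
from poresip.kmer_features import ReadFeatures


def _pred(prob, label):
    return Prediction(
        read_id=f"p{prob}",
        probability=prob,
        assigned_class=int(prob > 0.5),
        error_response=abs(label - prob),
        label=label,
    )


class TestMakeFolds:
    def test_equal_sizes(self):
        a = make_folds(100, 5, 1, seed=0)
        sizes = np.bincount(a[0])
        assert list(sizes) == [20] * 5

    def test_near_equal_sizes(self):
        a = make_folds(103, 5, 1, seed=0)
        sizes = sorted(np.bincount(a[0]), reverse=True)
        assert sizes == [21, 21, 21, 20, 20]

    def test_seeded_determinism_and_repetition_variation(self):
        a = make_folds(50, 5, 3, seed=9)
        b = make_folds(50, 5, 3, seed=9)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a[0], a[1])  # partitions differ across reps

    def test_too_few_reads(self):
        with pytest.raises(ValueError):
            make_folds(3, 5)


def _feat(read_id, c):
    v = np.zeros(4)
    return ReadFeatures(read_id=read_id, k=1, m=v, d=v, l=v, x=0.0,
                        present=np.ones(4, bool), c=c)


class TestBalanceClasses:
    def test_larger_class_subsampled(self):
        feats = [_feat(f"a{i}", 0) for i in range(600)] + [_feat(f"b{i}", 1) for i in range(400)]
        out = balance_classes(feats, seed=1)
        labels = [f.c for f in out]
        assert labels.count(0) == 400 and labels.count(1) == 400

    def test_already_balanced_unchanged(self):
        feats = [_feat(f"a{i}", 0) for i in range(5)] + [_feat(f"b{i}", 1) for i in range(5)]
        assert balance_classes(feats, seed=1) == feats

    def test_seeded_determinism(self):
        feats = [_feat(f"a{i}", 0) for i in range(30)] + [_feat(f"b{i}", 1) for i in range(10)]
        ids1 = [f.read_id for f in balance_classes(feats, seed=2)]
        ids2 = [f.read_id for f in balance_classes(feats, seed=2)]
        assert ids1 == ids2


class TestConfusion:
    def test_all_correct(self):
        preds = [_pred(0.9, 1)] * 50 + [_pred(0.1, 0)] * 50
        c = confusion(preds)
        assert (c.TP, c.TN, c.FP, c.FN) == (50, 50, 0, 0)

    def test_exact_half_counts_incorrect(self):
        c = confusion([_pred(0.5, 1), _pred(0.5, 0)])
        assert (c.TP, c.TN, c.FP, c.FN) == (0, 0, 1, 1)

    def test_hand_tally(self):
        preds = [
            _pred(0.9, 1), _pred(0.8, 1), _pred(0.3, 1),  # 2 TP, 1 FN
            _pred(0.2, 0), _pred(0.4, 0), _pred(0.45, 0), _pred(0.7, 0),  # 3 TN, 1 FP
            _pred(0.6, 1), _pred(0.55, 1),  # 2 TP
            _pred(0.95, 0),  # 1 FP
        ]
        c = confusion(preds)
        assert (c.TP, c.TN, c.FP, c.FN) == (4, 3, 2, 1)

    def test_unlabeled_rejected(self):
        p = Prediction("r", 0.9, 1)
        with pytest.raises(ValueError):
            confusion([p])


class TestMetrics:
    def test_perfect_and_inverted(self):
        assert f1(ConfusionCounts(50, 50, 0, 0)) == 1.0
        assert mcc(ConfusionCounts(50, 50, 0, 0)) == 1.0
        assert mcc(ConfusionCounts(0, 0, 50, 50)) == -1.0

    def test_hand_values(self):
        assert f1(ConfusionCounts(40, 0, 10, 10)) == pytest.approx(0.8)
        assert mcc(ConfusionCounts(40, 40, 10, 10)) == pytest.approx(0.6)

    def test_degenerate_undefined(self):
        assert f1(ConfusionCounts(0, 10, 0, 0)) is None
        assert mcc(ConfusionCounts(0, 10, 0, 0)) is None

    def test_against_sklearn_on_random_tables(self, rng):
        """Independent library implementations agree on 1000 random tables."""
        for _ in range(1000):
            tp, tn, fp, fn = rng.integers(0, 30, 4)
            y_true = [1] * tp + [0] * tn + [0] * fp + [1] * fn
            y_pred = [1] * tp + [0] * tn + [1] * fp + [0] * fn
            counts = ConfusionCounts(int(tp), int(tn), int(fp), int(fn))
            ours_f1 = f1(counts)
            if ours_f1 is not None and y_true:
                assert ours_f1 == pytest.approx(
                    f1_score(y_true, y_pred, zero_division=0), abs=1e-12
                )
            ours_mcc = mcc(counts)
            if ours_mcc is not None:
                assert ours_mcc == pytest.approx(
                    matthews_corrcoef(y_true, y_pred), abs=1e-9
                )


class TestFdrCurve:
    def test_perfect_classifier(self):
        preds = [_pred(0.99, 1)] * 5 + [_pred(0.01, 0)] * 5
        for pt in fdr_curve(preds, np.array([0.01, 0.2, 0.5])):
            assert pt.fdr == 0.0 and pt.fraction_classified == 1.0

    def test_uncertain_reads_unclassified(self):
        preds = [_pred(0.5, 1)] * 4
        (pt,) = fdr_curve(preds, np.array([0.4]))
        assert pt.fdr is None and pt.fraction_classified == 0.0

    def test_matches_brute_force(self, rng):
        preds = [
            _pred(float(p), int(c))
            for p, c in zip(rng.uniform(0, 1, 20), rng.integers(0, 2, 20))
        ]
        for t in (0.1, 0.3, 0.5):
            (pt,) = fdr_curve(preds, np.array([t]))
            selected = [p for p in preds if p.probability <= t or p.probability >= 1 - t]
            assert pt.fraction_classified == pytest.approx(len(selected) / 20)
            if selected:
                wrong = sum(
                    1 for p in selected if (p.probability > 0.5) != (p.label == 1)
                    or p.probability == 0.5
                )
                assert pt.fdr == pytest.approx(wrong / len(selected))
            else:
                assert pt.fdr is None

    def test_fraction_classified_monotone_in_cutoff(self, rng):
        preds = [
            _pred(float(p), int(c))
            for p, c in zip(rng.uniform(0, 1, 200), rng.integers(0, 2, 200))
        ]
        curve = fdr_curve(preds)
        fracs = [pt.fraction_classified for pt in curve]
        assert all(a <= b for a, b in zip(fracs, fracs[1:]))
        assert curve[-1].fraction_classified == 1.0  # t=0.5 classifies everything


class TestCutoffForFdr:
    def _curve(self, fdrs):
        cutoffs = np.linspace(0, 0.5, len(fdrs))
        return [
            FdrPoint(cutoff=float(c), fdr=f, fraction_classified=float(c) * 2)
            for c, f in zip(cutoffs, fdrs)
        ]

    def test_all_zero_returns_largest(self):
        pt = cutoff_for_fdr(self._curve([0.0] * 11), 0.05)
        assert pt.cutoff == 0.5

    def test_monotone_crossing(self):
        # fdr crosses 0.05 between cutoff 0.30 and 0.35
        cutoffs = np.round(np.arange(0.0, 0.55, 0.05), 2)
        curve = [
            FdrPoint(cutoff=float(c), fdr=(0.02 if c <= 0.30 else 0.08),
                     fraction_classified=float(c))
            for c in cutoffs
        ]
        assert cutoff_for_fdr(curve, 0.05).cutoff == pytest.approx(0.30)

    def test_unreachable_target(self):
        assert cutoff_for_fdr(self._curve([0.2] * 11), 0.05) is None

    def test_empty_curve_rejected(self):
        with pytest.raises(ValueError):
            cutoff_for_fdr([], 0.05)


class TestErrorResponseCurve:
    def test_all_zero_flat(self):
        preds = [_pred(1.0 - 1e-12, 1)] * 5
        curves = error_response_curve(preds)
        assert np.allclose(curves[1][:, 1], 0.0)

    def test_correct_fraction(self):
        preds = [
            Prediction("a", 0.9, 1, 0.1, 1),
            Prediction("b", 0.8, 1, 0.2, 1),
            Prediction("c", 0.4, 0, 0.6, 1),
            Prediction("d", 0.1, 0, 0.9, 1),
        ]
        curve = error_response_curve(preds)[1]
        assert np.mean(curve[:, 1] < 0.5) == pytest.approx(0.5)

    def test_non_decreasing(self, rng):
        preds = [
            _pred(float(p), int(c))
            for p, c in zip(rng.uniform(0, 1, 50), rng.integers(0, 2, 50))
        ]
        for curve in error_response_curve(preds).values():
            assert np.all(np.diff(curve[:, 1]) >= 0)
            assert curve[0, 0] == 0.0 and curve[-1, 0] == 1.0


@pytest.fixture(scope="module")
def cv_report():
    from poresip import synthetic_data as sd

    cfg = sd.GeneratorConfig(
        n_reads_per_class=100, k=1, read_length_mean=400,
        affected_fraction=1.0, effect_median_sd=0.8, seed=31,
    )
    feats, _ = sd.generate_features_direct(cfg)
    mc = ModelConfig(k=1, vi_iterations=1500, n_posterior_samples=300, seed=1)
    return crossvalidate(feats, mc, CvConfig(seed=3))


class TestCrossvalidate:
    def test_fifteen_splits(self, cv_report):
        assert len(cv_report.folds) == 15
        reps = {(f.repetition, f.fold) for f in cv_report.folds}
        assert len(reps) == 15

    def test_folds_partition_within_repetition(self):
        a = make_folds(100, 5, 3, seed=4)
        for rep in range(3):
            assert np.bincount(a[rep]).sum() == 100  # every read in exactly one fold

    def test_strong_effect_recovers_classes(self, cv_report):
        s = cv_report.summary()
        assert s.loc["mean", "rate_class0_test"] >= 0.85
        assert s.loc["mean", "rate_class1_test"] >= 0.85

    def test_aggregates_recomputable(self, cv_report):
        agg = cv_report.aggregate()
        s = cv_report.summary()
        assert s.loc["mean", "f1"] == pytest.approx(agg["f1"].mean())
        assert s.loc["std", "mcc"] == pytest.approx(agg["mcc"].std())

    def test_training_ignores_test_labels(self, rng):
        """The fitted posterior depends on the training fold only."""
        from poresip import glm_model as gm

        feats = [_feat(f"a{i}", i % 2) for i in range(40)]
        for f in feats:
            f.m = rng.normal(0, 1, 4)
            f.d = rng.normal(0, 1, 4)
        train, test = feats[:30], feats[30:]
        post1 = gm.fit(train, ModelConfig(k=1, vi_iterations=300, seed=6))
        for f in test:
            f.c = 1 - f.c  # shuffle test labels
        post2 = gm.fit(train, ModelConfig(k=1, vi_iterations=300, seed=6))
        np.testing.assert_array_equal(post1.beta, post2.beta)
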