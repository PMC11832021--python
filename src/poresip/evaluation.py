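"""Cross-validation protocol and classifier metrics.

The evaluation follows a triplicate five-fold scheme: each repetition
randomly partitions the labeled reads into five near-equal folds; four
folds train (after class balancing and the k-mer completeness filter) and
the fifth is held out, giving 15 train/test splits in total.  Performance
is summarized by confusion counts, F1, Matthews correlation, precision,
per-class error-response curves, and FDR as a function of the
error-response cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import glm_model
from .glm_model import ModelConfig, Prediction
from .kmer_features import ReadFeatures, filter_complete_reads, fit_boxcox_on_stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class FdrPoint:
    """FDR and classified fraction at one error-response cutoff.

    ``fdr`` is None when no read meets the cutoff (an empty classified set
    has no defined discovery rate).
    """

    cutoff: float
    fdr: float | None
    fraction_classified: float


@dataclass
class FoldResult:
    repetition: int
    fold: int
    counts_test: ConfusionCounts
    counts_train: ConfusionCounts
    rate_class0_test: float
    rate_class1_test: float
    rate_class0_train: float
    rate_class1_train: float
    f1: float | None
    mcc: float | None
    precision: float | None
    fdr_points: list[FdrPoint]
    predictions_test: list[Prediction] = field(default_factory=list)


@dataclass
class EvaluationReport:
    """Per-fold results plus aggregate mean ± sd across the 15 splits."""

    folds: list[FoldResult]

    def aggregate(self) -> pd.DataFrame:
        rows = []
        for fr in self.folds:
            rows.append(
                {
                    "repetition": fr.repetition,
                    "fold": fr.fold,
                    "rate_class0_test": fr.rate_class0_test,
                    "rate_class1_test": fr.rate_class1_test,
                    "rate_class0_train": fr.rate_class0_train,
                    "rate_class1_train": fr.rate_class1_train,
                    "f1": fr.f1,
                    "mcc": fr.mcc,
                    "precision": fr.precision,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> pd.DataFrame:
        agg = self.aggregate().drop(columns=["repetition", "fold"])
        return agg.agg(["mean", "std"])

    def pooled_test_predictions(self) -> list[Prediction]:
        out: list[Prediction] = []
        for fr in self.folds:
            out.extend(fr.predictions_test)
        return out


def make_folds(
    n_reads: int, n_folds: int = 5, n_repeats: int = 3, seed: int = 0
) -> np.ndarray:
    """Random fold assignments, shape (n_repeats, n_reads), values in [0, n_folds).

    Within each repetition fold sizes differ by at most one; the partitions
    are redrawn independently per repetition.
    """
    if n_reads < n_folds:
        raise ValueError(f"need at least {n_folds} reads for {n_folds} folds")
    rng = np.random.default_rng(seed)
    assignments = np.empty((n_repeats, n_reads), dtype=int)
    base = np.arange(n_reads) % n_folds
    for rep in range(n_repeats):
        assignments[rep] = rng.permutation(base)
    return assignments


def balance_classes(features: Sequence[ReadFeatures], seed: int = 0) -> list[ReadFeatures]:
    """Subsample the larger class (without replacement) to the smaller's size.

    Applied to training folds only; test folds keep their natural class mix.
    """
    idx0 = [i for i, f in enumerate(features) if f.c == 0]
    idx1 = [i for i, f in enumerate(features) if f.c == 1]
    if not idx0 or not idx1:
        raise ValueError("both classes must be present to balance")
    rng = np.random.default_rng(seed)
    n = min(len(idx0), len(idx1))
    keep = set(rng.choice(idx0, n, replace=False)) | set(rng.choice(idx1, n, replace=False))
    return [f for i, f in enumerate(features) if i in keep]


def confusion(preds: Sequence[Prediction]) -> ConfusionCounts:
    """Tally confusion counts; correct means error response < 0.5.

    A probability of exactly 0.5 (error response exactly 0.5) counts as
    incorrect for either true class.
    """
    tp = tn = fp = fn = 0
    for p in preds:
        if p.error_response is None or p.label is None:
            raise ValueError(f"prediction for {p.read_id!r} has no label")
        correct = p.error_response < 0.5
        if p.label == 1:
            tp += correct
            fn += not correct
        else:
            tn += correct
            fp += not correct
    return ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn)


def f1(counts: ConfusionCounts) -> float | None:
    """F1 = 2TP / (2TP + FP + FN); None when the denominator is zero."""
    denom = 2 * counts.TP + counts.FP + counts.FN
    return None if denom == 0 else 2 * counts.TP / denom


def mcc(counts: ConfusionCounts) -> float | None:
    """Matthews correlation coefficient; None when any marginal is zero."""
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    factors = [(tp + fp), (tp + fn), (tn + fp), (tn + fn)]
    if any(f == 0 for f in factors):
        return None
    return float((tp * tn - fp * fn) / np.sqrt(np.prod([float(f) for f in factors])))


def precision(counts: ConfusionCounts) -> float | None:
    denom = counts.TP + counts.FP
    return None if denom == 0 else counts.TP / denom


def default_cutoff_grid() -> np.ndarray:
    """101 cutoffs, step 0.005, spanning [0, 0.5]."""
    return np.round(np.linspace(0.0, 0.5, 101), 6)


def fdr_curve(
    preds: Sequence[Prediction], cutoffs: np.ndarray | None = None
) -> list[FdrPoint]:
    """FDR and classified fraction per cutoff.

    At cutoff t a read is classified when its probability is <= t or
    >= 1 - t; the FDR is the fraction of classified reads whose assigned
    class disagrees with the truth.
    """
    if cutoffs is None:
        cutoffs = default_cutoff_grid()
    probs = np.array([p.probability for p in preds])
    errs = np.array([p.error_response for p in preds], dtype=float)
    if np.any(np.isnan(errs)):
        raise ValueError("fdr_curve requires labeled predictions")
    n = probs.size
    points = []
    for t in cutoffs:
        classified = (probs <= t) | (probs >= 1.0 - t)
        n_cls = int(classified.sum())
        if n_cls == 0:
            points.append(FdrPoint(cutoff=float(t), fdr=None, fraction_classified=0.0))
            continue
        # a classified read is a false discovery when its error response
        # says the assigned class is wrong (error response >= 0.5)
        wrong = errs[classified] >= 0.5
        points.append(
            FdrPoint(
                cutoff=float(t),
                fdr=float(wrong.mean()),
                fraction_classified=n_cls / n,
            )
        )
    return points


def cutoff_for_fdr(curve: Sequence[FdrPoint], target_fdr: float) -> FdrPoint | None:
    """Largest cutoff whose empirical FDR is <= target; None if none qualifies."""
    if not curve:
        raise ValueError("empty FDR curve")
    qualifying = [pt for pt in curve if pt.fdr is not None and pt.fdr <= target_fdr]
    if not qualifying:
        return None
    return max(qualifying, key=lambda pt: pt.cutoff)


def error_response_curve(preds: Sequence[Prediction]) -> dict[int, np.ndarray]:
    """Sorted error responses per class with rank normalized to [0, 1].

    Returns, per class, an array of shape (n, 2): column 0 is the
    normalized rank, column 1 the ascending error response.
    """
    curves: dict[int, np.ndarray] = {}
    by_class: dict[int, list[float]] = {0: [], 1: []}
    for p in preds:
        if p.error_response is None or p.label is None:
            raise ValueError("error_response_curve requires labeled predictions")
        by_class[p.label].append(p.error_response)
    for cls, errs in by_class.items():
        errs = np.sort(np.array(errs))
        n = errs.size
        xs = np.linspace(0.0, 1.0, n) if n > 1 else np.zeros(n)
        curves[cls] = np.column_stack([xs, errs])
    return curves


@dataclass
class CvConfig:
    n_folds: int = 5
    n_repeats: int = 3
    seed: int = 0
    keep_predictions: bool = True


def crossvalidate(
    features: Sequence[ReadFeatures] | None,
    model_config: ModelConfig,
    cv_config: CvConfig | None = None,
    raw_stats: Sequence | None = None,
) -> EvaluationReport:
    """Run the full repeated five-fold protocol.

    Per split: balance training classes, keep only training reads that
    contain every k-mer, fit the Box-Cox λs and feature centering on the
    training portion alone, fit the model, and score the untouched test
    fold.  When ``raw_stats`` is given (``features`` may then be None),
    λs are re-fitted per split from the training reads' raw statistics and
    the features re-assembled; otherwise the provided (pre-transformed)
    features are used as-is.
    """
    from .kmer_features import assemble_features

    cv = cv_config or CvConfig()
    if raw_stats is not None:
        labels = [st.label for st in raw_stats]
        n_reads = len(raw_stats)
    else:
        if features is None:
            raise ValueError("need features or raw_stats")
        labels = [f.c for f in features]
        n_reads = len(features)
    if any(c is None for c in labels):
        raise ValueError("cross-validation requires labeled reads")
    for cls in (0, 1):
        if labels.count(cls) < cv.n_folds:
            raise ValueError(f"fewer than {cv.n_folds} reads in class {cls}")
    assignments = make_folds(n_reads, cv.n_folds, cv.n_repeats, cv.seed)

    folds: list[FoldResult] = []
    for rep in range(cv.n_repeats):
        for fold_id in range(cv.n_folds):
            test_mask = assignments[rep] == fold_id
            train_idx = np.flatnonzero(~test_mask)
            test_idx = np.flatnonzero(test_mask)
            split_seed = cv.seed * 1009 + rep * 101 + fold_id

            if raw_stats is not None:
                train_stats = [raw_stats[i] for i in train_idx]
                complete_stats = [st for st in train_stats if st.present.all()]
                mad_fit, dwell_fit = fit_boxcox_on_stats(complete_stats)
                train_feats = [
                    assemble_features(st, mad_fit, dwell_fit) for st in train_stats
                ]
                test_feats = [
                    assemble_features(raw_stats[i], mad_fit, dwell_fit) for i in test_idx
                ]
                boxcox_fits = (mad_fit, dwell_fit)
            else:
                train_feats = [features[i] for i in train_idx]
                test_feats = [features[i] for i in test_idx]
                boxcox_fits = None

            train_feats = balance_classes(train_feats, seed=split_seed)
            train_feats = filter_complete_reads(train_feats)

            fit_config = ModelConfig(**{**model_config.__dict__, "seed": split_seed})
            posterior = glm_model.fit(train_feats, fit_config, boxcox_fits=boxcox_fits)
            preds_test = glm_model.predict(posterior, test_feats)
            preds_train = glm_model.predict(posterior, train_feats)

            counts_test = confusion(preds_test)
            counts_train = confusion(preds_train)
            folds.append(
                FoldResult(
                    repetition=rep,
                    fold=fold_id,
                    counts_test=counts_test,
                    counts_train=counts_train,
                    rate_class0_test=_class_rate(counts_test, 0),
                    rate_class1_test=_class_rate(counts_test, 1),
                    rate_class0_train=_class_rate(counts_train, 0),
                    rate_class1_train=_class_rate(counts_train, 1),
                    f1=f1(counts_test),
                    mcc=mcc(counts_test),
                    precision=precision(counts_test),
                    fdr_points=fdr_curve(preds_test),
                    predictions_test=list(preds_test) if cv.keep_predictions else [],
                )
            )
            logger.info(
                "rep %d fold %d: test rates %.3f / %.3f",
                rep,
                fold_id,
                folds[-1].rate_class0_test,
                folds[-1].rate_class1_test,
            )
    return EvaluationReport(folds=folds)


def _class_rate(counts: ConfusionCounts, cls: int) -> float:
    if cls == 1:
        denom = counts.TP + counts.FN
        return counts.TP / denom if denom else float("nan")
    denom = counts.TN + counts.FP
    return counts.TN / denom if denom else float("nan")
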