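"""Evaluation protocol: splits, folds, and the binary metric suite.

The protocol mirrors how this model family is assessed: a stratified
70/30 train/test split, stratified k = 10 cross-validation (so a
100,000-record cohort yields ten folds of exactly 10,000), and the
metric suite — accuracy, precision, recall (sensitivity), specificity,
F1, the misclassification (error) rate, ROC-AUC and average precision.
The error rate is computed both as (FP + FN)/total and as 1 − accuracy;
the two are the same identity written two ways and the report carries
the shared value.

AUC is computed by a threshold sweep with trapezoidal area, which
equals the fraction of correctly ordered positive–negative pairs with
ties counted 1/2 (the Mann–Whitney statistic); the brute-force pairwise
count is kept in the test suite as the independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .exceptions import ValidationError
from .fis import FISConfig, triage
from .ioformats import PatientRecord, binarize_target
from .mgru import GRUModel, NetworkConfig, TrainState, predict_proba, train
from .preprocess import Encoder, fit_encoder

__all__ = [
    "ConfusionCounts",
    "CrossValidationResult",
    "FoldPlan",
    "MetricReport",
    "SplitPlan",
    "average_precision",
    "confusion",
    "cross_validate",
    "kfold_plan",
    "metric_report",
    "roc_auc",
    "stratified_split",
]


# --------------------------------------------------------------------------
# splits
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class SplitPlan:
    train_idx: tuple[int, ...]
    test_idx: tuple[int, ...]
    fraction: float
    seed: int


@dataclass(frozen=True)
class FoldPlan:
    folds: tuple[tuple[int, ...], ...]
    seed: int

    @property
    def k(self) -> int:
        return len(self.folds)


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.ndim != 1 or labels.size < 2:
        raise ValidationError("labels must be a 1-D array with n >= 2")
    if len(np.unique(labels)) < 2:
        raise ValidationError("both classes must be present")
    return labels


def stratified_split(labels: Sequence[int], fraction: float = 0.7, seed: int = 0) -> SplitPlan:
    """Disjoint, exhaustive train/test indices with preserved class balance.

    The train share is round(fraction·n) exactly; per-class train counts
    are apportioned by largest remainder, so each class's proportion is
    preserved to within one record.  Deterministic per seed.
    """
    labels = _check_labels(np.asarray(labels))
    n = labels.size
    n_train = int(round(fraction * n))
    rng = np.random.default_rng(seed)
    classes = np.unique(labels)
    targets = {c: fraction * np.sum(labels == c) for c in classes}
    floors = {c: int(np.floor(t)) for c, t in targets.items()}
    leftover = n_train - sum(floors.values())
    by_rem = sorted(classes, key=lambda c: (-(targets[c] - floors[c]), c))
    take = dict(floors)
    for c in by_rem[:leftover]:
        take[c] += 1
    train_idx: list[int] = []
    test_idx: list[int] = []
    for c in classes:
        members = np.flatnonzero(labels == c)
        rng.shuffle(members)
        train_idx.extend(members[: take[c]].tolist())
        test_idx.extend(members[take[c] :].tolist())
    train_idx.sort()
    test_idx.sort()
    return SplitPlan(tuple(train_idx), tuple(test_idx), fraction, seed)


def kfold_plan(labels: Sequence[int], k: int = 10, seed: int = 0) -> FoldPlan:
    """Shuffled, stratified folds; sizes differ by at most one.

    Within each class the shuffled members are dealt out a base share
    per fold, with the remainder topping up the currently smallest
    folds (ties to the earliest index) — so when k divides n all folds
    are exactly equal.
    """
    labels = np.asarray(labels)
    if labels.ndim != 1 or labels.size == 0:
        raise ValidationError("labels must be a nonempty 1-D array")
    n = labels.size
    if not 2 <= k <= n:
        raise ValidationError(f"k must lie in [2, n]; got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for c in np.unique(labels):
        members = np.flatnonzero(labels == c)
        rng.shuffle(members)
        base, rem = divmod(members.size, k)
        # folds sorted by (current size, index): remainder to the smallest
        order = sorted(range(k), key=lambda f: (len(folds[f]), f))
        counts = [base] * k
        for f in order[:rem]:
            counts[f] += 1
        pos = 0
        for f in range(k):
            folds[f].extend(members[pos : pos + counts[f]].tolist())
            pos += counts[f]
    return FoldPlan(tuple(tuple(sorted(f)) for f in folds), seed)


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionCounts:
    """2×2 cross-tabulation; the positive class is risk present (1)."""
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    if yt.shape != yp.shape or yt.ndim != 1:
        raise ValidationError("true and predicted labels must be equal-length 1-D arrays")
    for arr in (yt, yp):
        if not np.all((arr == 0) | (arr == 1)):
            raise ValidationError("labels must be binary (0/1)")
    return ConfusionCounts(
        tp=int(np.sum((yt == 1) & (yp == 1))),
        tn=int(np.sum((yt == 0) & (yp == 0))),
        fp=int(np.sum((yt == 0) & (yp == 1))),
        fn=int(np.sum((yt == 1) & (yp == 0))),
    )


@dataclass
class MetricReport:
    accuracy: float
    precision: float
    recall: float
    specificity: float
    f1: float
    error_rate: float
    confusion: ConfusionCounts
    auc: float | None = None
    average_precision: float | None = None
    undefined: tuple[str, ...] = ()  # metrics whose denominator was zero

    def as_dict(self) -> dict:
        out = {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "specificity": self.specificity,
            "f1": self.f1,
            "error_rate": self.error_rate,
            "tp": self.confusion.tp,
            "tn": self.confusion.tn,
            "fp": self.confusion.fp,
            "fn": self.confusion.fn,
        }
        if self.auc is not None:
            out["auc"] = self.auc
        if self.average_precision is not None:
            out["average_precision"] = self.average_precision
        if self.undefined:
            out["undefined"] = list(self.undefined)
        return out


def _ratio(num: int, den: int, name: str, undefined: list[str]) -> float:
    if den == 0:
        undefined.append(name)
        return 0.0
    return num / den


def metric_report(counts: ConfusionCounts) -> MetricReport:
    """All threshold-fixed metrics from a confusion table.

    error_rate is (FP + FN)/total, identically 1 − accuracy.  Ratios
    with a zero denominator are reported as 0 and listed in
    ``undefined``.
    """
    if counts.total == 0:
        raise ValidationError("confusion counts are all zero")
    undefined: list[str] = []
    accuracy = (counts.tp + counts.tn) / counts.total
    precision = _ratio(counts.tp, counts.tp + counts.fp, "precision", undefined)
    recall = _ratio(counts.tp, counts.tp + counts.fn, "recall", undefined)
    specificity = _ratio(counts.tn, counts.tn + counts.fp, "specificity", undefined)
    if precision + recall == 0:
        undefined.append("f1")
        f1 = 0.0
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    error_rate = (counts.fp + counts.fn) / counts.total
    return MetricReport(
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        specificity=specificity,
        f1=f1,
        error_rate=error_rate,
        confusion=counts,
        undefined=tuple(undefined),
    )


def roc_auc(y_true: Sequence[int], scores: Sequence[float]) -> tuple[np.ndarray, float]:
    """ROC points (FPR, TPR) over descending unique-score thresholds + area.

    The trapezoidal area equals the probability that a random positive
    outscores a random negative, with ties counted one half.
    """
    yt = np.asarray(y_true)
    s = np.asarray(scores, dtype=float)
    if yt.shape != s.shape:
        raise ValidationError("labels and scores must be equal length")
    n_pos = int(np.sum(yt == 1))
    n_neg = int(np.sum(yt == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("ROC needs both classes present")
    order = np.argsort(-s, kind="stable")
    yt_sorted = yt[order]
    s_sorted = s[order]
    # collapse tied scores into single thresholds
    distinct = np.r_[np.flatnonzero(np.diff(s_sorted)), s_sorted.size - 1]
    tps = np.cumsum(yt_sorted == 1)[distinct]
    fps = np.cumsum(yt_sorted == 0)[distinct]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    points = np.column_stack([fpr, tpr])
    return points, auc


def average_precision(y_true: Sequence[int], scores: Sequence[float]) -> float:
    """Mean over positives of precision at each positive's rank.

    Records are ranked by descending score; tied scores keep their
    original order (stable sort), which is the documented tie rule.
    """
    yt = np.asarray(y_true)
    s = np.asarray(scores, dtype=float)
    if yt.shape != s.shape:
        raise ValidationError("labels and scores must be equal length")
    n_pos = int(np.sum(yt == 1))
    if n_pos == 0:
        raise ValidationError("average precision needs at least one positive")
    order = np.argsort(-s, kind="stable")
    ranked = yt[order]
    hits = np.cumsum(ranked == 1)
    ranks = np.arange(1, ranked.size + 1)
    precisions_at_pos = (hits / ranks)[ranked == 1]
    return float(np.mean(precisions_at_pos))


def scored_report(y_true: Sequence[int], scores: Sequence[float], threshold: float = 0.5) -> MetricReport:
    """Full report (threshold metrics + AUC + AP) from probabilities."""
    yt = np.asarray(y_true)
    s = np.asarray(scores, dtype=float)
    report = metric_report(confusion(yt, (s >= threshold).astype(int)))
    report.auc = roc_auc(yt, s)[1]
    report.average_precision = average_precision(yt, s)
    return report


# --------------------------------------------------------------------------
# cross-validation driver
# --------------------------------------------------------------------------
@dataclass
class CrossValidationResult:
    fold_reports: list[MetricReport]
    mean: dict[str, float]
    sd: dict[str, float]
    plan: FoldPlan
    n_records: int

    def as_dict(self) -> dict:
        return {
            "k": self.plan.k,
            "n_records": self.n_records,
            "folds": [r.as_dict() for r in self.fold_reports],
            "mean": self.mean,
            "sd": self.sd,
        }


_AGGREGATED = ("accuracy", "precision", "recall", "specificity", "f1", "error_rate",
               "auc", "average_precision")


def _labels_of(records: Sequence[PatientRecord]) -> np.ndarray:
    labels = []
    for r in records:
        if r.raw_target is None:
            raise ValidationError(f"record uid={r.uid} has no target")
        labels.append(binarize_target(r.raw_target))
    return np.asarray(labels)


def cross_validate(
    records: Sequence[PatientRecord],
    network: NetworkConfig,
    fis_config: FISConfig | None = None,
    mode: Literal["with_triage", "full_cohort"] = "full_cohort",
    k: int = 10,
    seed: int = 0,
    epochs: int | None = None,
    threshold: float = 0.5,
) -> CrossValidationResult:
    """Stratified k-fold evaluation with no train/test leakage.

    Per fold: the encoder is fitted on the training portion only, the
    model is trained on it, and the untouched holdout is scored.  In
    ``with_triage`` mode the fuzzy triage stage first routes the cohort
    and only high-risk records reach the model (the pipeline's
    deployment path); ``full_cohort`` bypasses triage so the classifier
    is judged on everyone.
    """
    records = list(records)
    if mode == "with_triage":
        records = triage(records, fis_config).routed
        if not records:
            raise ValidationError("triage routed no records; nothing to cross-validate")
    labels = _labels_of(records)
    plan = kfold_plan(labels, k=k, seed=seed)
    fold_reports: list[MetricReport] = []
    for f, holdout in enumerate(plan.folds):
        holdout_set = set(holdout)
        train_records = [r for i, r in enumerate(records) if i not in holdout_set]
        test_records = [records[i] for i in holdout]
        encoder = fit_encoder(train_records)
        fold_cfg = NetworkConfig(**{**_config_dict(network), "seed": network.seed + f})
        X_train = encoder.encode_batch(train_records)
        y_train = _labels_of(train_records)
        model, _ = train(X_train, y_train, fold_cfg, epochs=epochs)
        X_test = encoder.encode_batch(test_records)
        y_test = labels[list(holdout)]
        scores = predict_proba(model, X_test)
        fold_reports.append(scored_report(y_test, scores, threshold=threshold))
    mean = {
        m: float(np.mean([getattr(r, m) for r in fold_reports])) for m in _AGGREGATED
    }
    sd = {m: float(np.std([getattr(r, m) for r in fold_reports], ddof=1)) for m in _AGGREGATED}
    return CrossValidationResult(fold_reports, mean, sd, plan, len(records))


def _config_dict(config: NetworkConfig) -> dict:
    from dataclasses import asdict

    d = asdict(config)
    from .mgru import ActivationConfig

    d["activation"] = ActivationConfig(**d["activation"])
    return d


def split_evaluate(
    records: Sequence[PatientRecord],
    network: NetworkConfig,
    fraction: float = 0.7,
    seed: int = 0,
    epochs: int | None = None,
    threshold: float = 0.5,
) -> tuple[MetricReport, SplitPlan]:
    """Single stratified 70/30 train/test evaluation."""
    records = list(records)
    labels = _labels_of(records)
    plan = stratified_split(labels, fraction=fraction, seed=seed)
    train_records = [records[i] for i in plan.train_idx]
    test_records = [records[i] for i in plan.test_idx]
    encoder = fit_encoder(train_records)
    model, _ = train(encoder.encode_batch(train_records), _labels_of(train_records), network, epochs=epochs)
    scores = predict_proba(model, encoder.encode_batch(test_records))
    return scored_report(labels[list(plan.test_idx)], scores, threshold=threshold), plan
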