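"""Train/test split, confusion-matrix metric suite, ROC, baselines, run summaries.

Conventions: the positive class is ADHD = 1.  ``balanced_auc`` implements the
balanced-accuracy form 0.5 * (TPR + TNR) — reported both on the 0-1 scale and
as a percentage — alongside a standard trapezoidal ROC AUC; the two measure
different things and reports carry both, labeled.

Zero-denominator rates (e.g. precision when nothing is predicted positive)
are reported as the module sentinel ``UNDEFINED`` (NaN), never silently 0;
``is_defined`` tests for it.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.model_selection import train_test_split

#: Sentinel for metrics whose denominator is zero (documented; test with is_defined).
UNDEFINED: float = float("nan")


def is_defined(value: float) -> bool:
    return not math.isnan(value)


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/TN/FP/FN counts with positive class = 1 (ADHD)."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be nonnegative")
        if self.total < 1:
            raise ValueError("confusion matrix must contain at least one instance")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def as_table(self) -> str:
        return (
            "                 predicted 0   predicted 1\n"
            f"  actual 0 (ctl) {self.tn:>11d}   {self.fp:>11d}\n"
            f"  actual 1 (adhd){self.fn:>11d}   {self.tp:>11d}"
        )


@dataclass(frozen=True)
class MetricReport:
    """All derived rates; ``recall`` is sensitivity/TPR, ``specificity`` is TNR."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    specificity: float
    balanced_auc: float            # 0.5 * (TPR + TNR), 0-1 scale
    balanced_auc_percent: float    # same * 100 (the printed-formula scale)
    misclassification_rate: float
    fpr: float
    empirical_roc_auc: float = UNDEFINED

    @property
    def sensitivity(self) -> float:
        return self.recall

    @property
    def tpr(self) -> float:
        return self.recall

    @property
    def tnr(self) -> float:
        return self.specificity

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def split(values: np.ndarray, labels: np.ndarray, test_fraction: float = 0.2,
          seed: int = 0, stratified: bool = True
          ) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/test index partition (default 80/20, stratified)."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    labels = np.asarray(labels)
    idx = np.arange(len(labels))
    strat = labels if stratified else None
    if stratified and np.min(np.bincount(labels)) < 2:
        raise ValueError("stratified split needs >= 2 instances per class")
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, random_state=seed, stratify=strat)
    return np.sort(train_idx), np.sort(test_idx)


def confusion(true_labels: np.ndarray, predicted_labels: np.ndarray) -> ConfusionMatrix:
    """Tally the 2x2 table; labels must be binary vectors of equal length."""
    t = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {p.shape}")
    if t.size and (not np.isin(t, (0, 1)).all() or not np.isin(p, (0, 1)).all()):
        raise ValueError("labels must be binary")
    return ConfusionMatrix(
        tp=int(np.sum((t == 1) & (p == 1))),
        tn=int(np.sum((t == 0) & (p == 0))),
        fp=int(np.sum((t == 0) & (p == 1))),
        fn=int(np.sum((t == 1) & (p == 0))),
    )


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else UNDEFINED


def compute_metrics(cm: ConfusionMatrix, roc_auc: float = UNDEFINED) -> MetricReport:
    """Derive the full rate suite from integer counts.

    accuracy = (TP+TN)/S, precision = TP/(TP+FP), recall = TP/(TP+FN),
    F1 = 2PR/(P+R), specificity = TN/(TN+FP), balanced AUC = (TPR+TNR)/2,
    misclassification = (FP+FN)/S.  The misclassification rate is computed as
    1 - accuracy, which equals (FP+FN)/S exactly in real arithmetic (the
    counts sum to S) and guarantees the exact floating-point complement.
    """
    s = cm.total
    accuracy = (cm.tp + cm.tn) / s
    precision = _ratio(cm.tp, cm.tp + cm.fp)
    recall = _ratio(cm.tp, cm.tp + cm.fn)
    specificity = _ratio(cm.tn, cm.tn + cm.fp)
    fpr = 1.0 - specificity if is_defined(specificity) else UNDEFINED
    if is_defined(precision) and is_defined(recall) and (precision + recall) > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1 = UNDEFINED
    if is_defined(recall) and is_defined(specificity):
        bal = 0.5 * (recall + specificity)
    else:
        bal = UNDEFINED
    return MetricReport(
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f1=f1,
        specificity=specificity,
        balanced_auc=bal,
        balanced_auc_percent=bal * 100 if is_defined(bal) else UNDEFINED,
        misclassification_rate=1.0 - accuracy,
        fpr=fpr,
        empirical_roc_auc=roc_auc,
    )


def roc_and_auc(scores: np.ndarray, true_labels: np.ndarray
                ) -> tuple[np.ndarray, float]:
    """ROC points from a sweep over unique score thresholds + trapezoidal AUC.

    Returns an array of (FPR, TPR) rows ordered from (0,0) to (1,1).
    """
    scores = np.asarray(scores, dtype=float)
    t = np.asarray(true_labels, dtype=int)
    if scores.shape != t.shape:
        raise ValueError("scores and labels must align")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    n_pos = int((t == 1).sum())
    n_neg = int((t == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_labels = t[order]
    tps = np.cumsum(sorted_labels == 1)
    fps = np.cumsum(sorted_labels == 0)
    # keep only the last index of each tied-score run (one operating point per threshold)
    distinct = np.r_[np.diff(sorted_scores) != 0, True]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def run_baselines(train_features: np.ndarray, train_labels: np.ndarray,
                  test_features: np.ndarray, test_labels: np.ndarray,
                  seed: int = 0, n_estimators: int = 100
                  ) -> dict[str, MetricReport]:
    """Seeded Random Forest and AdaBoost references evaluated on the test split."""
    models = {
        "random_forest": RandomForestClassifier(
            n_estimators=n_estimators, random_state=seed),
        "adaboost": AdaBoostClassifier(n_estimators=n_estimators, random_state=seed),
    }
    reports: dict[str, MetricReport] = {}
    for name, clf in models.items():
        clf.fit(train_features, train_labels)
        pred = clf.predict(test_features)
        scores = clf.predict_proba(test_features)[:, 1]
        _, auc = roc_and_auc(scores, test_labels)
        reports[name] = compute_metrics(confusion(test_labels, pred), roc_auc=auc)
    return reports


@dataclass(frozen=True)
class RunSummary:
    """Mean, SD and t-based 95% CI of one metric over repeated seeded runs."""

    metric: str
    n_runs: int
    mean: float
    sd: float
    ci_lower: float
    ci_upper: float


def summarize_runs(values: Sequence[float], metric: str = "metric",
                   confidence: float = 0.95) -> RunSummary:
    """t-interval: mean +/- t_{(1+c)/2, n-1} * SD / sqrt(n); needs n >= 2."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need at least 2 runs for an interval")
    if np.ptp(v) == 0:                 # constant runs: exact degenerate interval
        c = float(v[0])
        return RunSummary(metric, len(v), c, 0.0, c, c)
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    tcrit = float(stats.t.ppf(0.5 + confidence / 2, df=len(v) - 1))
    half = tcrit * sd / math.sqrt(len(v))
    return RunSummary(metric, len(v), mean, sd, mean - half, mean + half)


def repeated_evaluation(run: Callable[[int], Mapping[str, float]],
                        n_runs: int = 20, base_seed: int = 0
                        ) -> dict[str, RunSummary]:
    """Repeat a seeded evaluation and summarize each metric with a 95% t-CI.

    ``run`` maps a seed to a metric dict; seeds are base_seed .. base_seed +
    n_runs - 1.  A failed run is excluded with a warning entry rather than
    aborting the summary.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    results: dict[str, list[float]] = {}
    failures: list[tuple[int, str]] = []
    for i in range(n_runs):
        try:
            metrics = run(base_seed + i)
        except Exception as exc:  # noqa: BLE001 - summary must survive run failures
            failures.append((base_seed + i, str(exc)))
            continue
        for k, val in metrics.items():
            results.setdefault(k, []).append(float(val))
    summaries = {k: summarize_runs(v, metric=k) for k, v in results.items()
                 if len(v) >= 2}
    if failures:
        import warnings
        warnings.warn(f"{len(failures)} runs failed and were excluded: {failures}",
                      stacklevel=2)
    return summaries


def compare_models(metric_runs_a: Sequence[float], metric_runs_b: Sequence[float]
                   ) -> tuple[float, float, float]:
    """Welch two-sample t-test on per-run metric values.

    Returns (statistic, degrees of freedom, p).  When both samples have zero
    variance and equal means the difference is exactly zero and p = 1 by
    convention; zero variance with unequal means yields p = 0.
    """
    a = np.asarray(metric_runs_a, dtype=float)
    b = np.asarray(metric_runs_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 runs per model")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        return math.inf, float(len(a) + len(b) - 2), 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)
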