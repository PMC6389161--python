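"""Evaluation metrics and the bootstrap comparison protocol.

Metrics: ROC AUC (Mann-Whitney form), Matthews correlation coefficient and
accuracy from a 2x2 confusion table, plus Pearson correlation of score
vectors. The protocol draws repeated random subsets (default 100 subsets of
25% of the proteins, without replacement), recomputes each metric per
subset, and reports mean +/- standard deviation; paired differences between
two predictors are tested with a paired t-test after an Anderson-Darling
normality check.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class EvalConfig:
    n_bootstrap: int = 100
    bootstrap_fraction: float = 0.25
    decision_threshold: float = 0.5
    rng_seed: int = 0
    alpha: float = 0.05
    with_replacement: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.bootstrap_fraction <= 1.0:
            raise ValueError("bootstrap_fraction must be in (0, 1]")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")


@dataclasses.dataclass(frozen=True)
class MetricSummary:
    mean: float
    std: float
    replicates: np.ndarray


@dataclasses.dataclass(frozen=True)
class EvaluationReport:
    auc: MetricSummary
    mcc: MetricSummary
    accuracy: MetricSummary

    def to_tsv_row(self, label: str = "") -> str:
        cells = [label]
        for m in (self.auc, self.mcc, self.accuracy):
            cells.append(f"{m.mean:.4f}±{m.std:.4f}")
        return "\t".join(cells)


def _check_two_class(labels: np.ndarray) -> np.ndarray:
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")
    return y


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve (probability a positive outranks a negative)."""
    y = _check_two_class(labels)
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def mcc(tp: int, fp: int, tn: int, fn: int) -> float:
    """Matthews correlation coefficient; 0 when any marginal is empty."""
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("counts must be non-negative")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(denom))


def accuracy(tp: int, fp: int, tn: int, fn: int) -> float:
    total = tp + fp + tn + fn
    if total == 0:
        raise ValueError("empty confusion table")
    return (tp + tn) / total


def confusion_counts(scores, labels, threshold: float = 0.5):
    """(tp, fp, tn, fn) at a score threshold (predict positive if > threshold)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    pred = s > threshold
    tp = int(np.count_nonzero(pred & y))
    fp = int(np.count_nonzero(pred & ~y))
    tn = int(np.count_nonzero(~pred & ~y))
    fn = int(np.count_nonzero(~pred & y))
    return tp, fp, tn, fn


def bootstrap_evaluate(
    scores, labels, config: EvalConfig = EvalConfig(), max_retries: int = 100
) -> EvaluationReport:
    """Subset-resampling evaluation: AUC/MCC/accuracy mean +/- std.

    Each replicate evaluates a random subset of round(fraction * n)
    proteins drawn without replacement (the protocol's "randomly chosen
    proteins"; classical with-replacement resampling is available via
    ``with_replacement``). Single-class subsets are redrawn.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(_check_two_class(labels), dtype=int)
    n = s.size
    size = max(2, round(config.bootstrap_fraction * n))
    rng = np.random.default_rng(config.rng_seed)
    aucs, mccs, accs = [], [], []
    for _ in range(config.n_bootstrap):
        for retry in range(max_retries):
            idx = rng.choice(n, size=size, replace=config.with_replacement)
            ys = y[idx]
            if np.unique(ys).size == 2:
                break
            if retry == max_retries - 1:
                raise ValueError(
                    "could not draw a two-class subset within retry budget"
                )
        ss = s[idx]
        aucs.append(roc_auc(ss, ys))
        tp, fp, tn, fn = confusion_counts(ss, ys, config.decision_threshold)
        mccs.append(mcc(tp, fp, tn, fn))
        accs.append(accuracy(tp, fp, tn, fn))
    def summarize(vals):
        arr = np.asarray(vals)
        return MetricSummary(float(arr.mean()), float(arr.std()), arr)
    return EvaluationReport(summarize(aucs), summarize(mccs), summarize(accs))


def paired_t_test(a, b) -> tuple[float, float]:
    """Classical paired t-test on matched replicate metrics; (t, two-sided p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 2:
        raise ValueError("need matched samples of length >= 2")
    d = a - b
    if np.var(d, ddof=1) == 0.0:
        raise ValueError("paired differences have zero variance")
    result = stats.ttest_rel(a, b)
    return float(result.statistic), float(result.pvalue)


_AD_LEVELS = {0.15: 0, 0.10: 1, 0.05: 2, 0.025: 3, 0.01: 4}


def anderson_darling_normal(sample, alpha: float = 0.05) -> tuple[float, bool]:
    """Anderson-Darling normality test; returns (A^2, reject-normality flag)."""
    x = np.asarray(sample, dtype=float)
    if x.size < 8:
        raise ValueError("Anderson-Darling test needs n >= 8")
    if alpha not in _AD_LEVELS:
        raise ValueError(f"alpha must be one of {sorted(_AD_LEVELS)}")
    import warnings

    with warnings.catch_warnings():
        # scipy >= 1.17 warns about the future `method` parameter; the
        # critical-value comparison below is the classical tabulated test
        warnings.simplefilter("ignore", FutureWarning)
        result = stats.anderson(x, dist="norm")
    critical = result.critical_values[_AD_LEVELS[alpha]]
    return float(result.statistic), bool(result.statistic > critical)


def pearson_correlation(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need two aligned vectors of length >= 2")
    if x.std() == 0.0 or y.std() == 0.0:
        raise ValueError("Pearson correlation undefined for constant input")
    return float(stats.pearsonr(x, y).statistic)
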