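"""Three-stage per-outcome feature selection.

1. Relevance filter: keep features whose absolute point-biserial correlation
   with the binary outcome reaches a multiple (default 2) of the mean
   absolute correlation over all features; a ranked top-``min_retained``
   fallback guards against an empty survivor set.
2. Redundancy filter: greedy scan in decreasing relevance; drop any feature
   whose absolute Pearson correlation with an already-kept feature exceeds
   the threshold (default 0.7), keeping the more relevant member of a pair.
3. Wrapper: start from the most relevant candidate and scan the rest once
   in rank order, accepting a candidate only if it strictly improves the
   mean stratified cross-validated AUC of a logistic model.

The whole procedure is deterministic given the fold-assignment seed.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .models import fit_logistic_stable, sigmoid, standardize_params
from .outcomes import OutcomeLabel

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class SelectionConfig:
    relevance_multiplier: float = 2.0
    redundancy_threshold: float = 0.7
    cv_folds: int = 5
    min_retained: int = 10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.relevance_multiplier <= 0:
            raise ValueError("relevance_multiplier must be > 0")
        if not 0.0 < self.redundancy_threshold <= 1.0:
            raise ValueError("redundancy_threshold must be in (0, 1]")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclasses.dataclass(frozen=True)
class TraceEntry:
    candidate: int
    auc_before: float
    auc_after: float
    accepted: bool


@dataclasses.dataclass(frozen=True)
class SelectionResult:
    outcome: OutcomeLabel | None
    relevance_survivors: tuple[int, ...]
    redundancy_survivors: tuple[int, ...]
    selected: tuple[int, ...]
    cv_auc_trace: tuple[TraceEntry, ...]

    def __post_init__(self) -> None:
        if not set(self.selected) <= set(self.redundancy_survivors):
            raise ValueError("selected must be a subset of redundancy survivors")
        if not set(self.redundancy_survivors) <= set(self.relevance_survivors):
            raise ValueError(
                "redundancy survivors must be a subset of relevance survivors"
            )

    def to_text(self) -> str:
        """Audit report: one line per wrapper-trace entry."""
        lines = [
            f"outcome\t{self.outcome.value if self.outcome else 'NA'}",
            f"relevance_survivors\t{len(self.relevance_survivors)}",
            f"redundancy_survivors\t{len(self.redundancy_survivors)}",
            f"selected\t{','.join(map(str, self.selected))}",
            "candidate\tauc_before\tauc_after\taccepted",
        ]
        for e in self.cv_auc_trace:
            lines.append(
                f"{e.candidate}\t{e.auc_before:.6f}\t{e.auc_after:.6f}\t"
                f"{int(e.accepted)}"
            )
        return "\n".join(lines) + "\n"


def point_biserial(feature_values: np.ndarray, labels: np.ndarray) -> float:
    """Pearson correlation between a feature and 0/1 labels; 0 if constant."""
    x = np.asarray(feature_values, dtype=float)
    y = np.asarray(labels, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need two aligned samples of length >= 2")
    if np.unique(y).size < 2:
        raise ValueError("labels contain a single class; correlation undefined")
    sx = x.std()
    if sx == 0.0:
        return 0.0
    return float(((x - x.mean()) @ (y - y.mean())) / (x.size * sx * y.std()))


def biserial_vector(matrix: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Point-biserial correlation of every column; constant columns get 0."""
    X = np.asarray(matrix, dtype=float)
    y = np.asarray(labels, dtype=float)
    if np.unique(y).size < 2:
        raise ValueError("labels contain a single class; correlation undefined")
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = X.std(axis=0)
    sy = y.std()
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc.T @ yc) / (X.shape[0] * sx * sy)
    return np.where(sx == 0.0, 0.0, r)


def relevance_filter(
    matrix: np.ndarray,
    labels: np.ndarray,
    config: SelectionConfig = SelectionConfig(),
    abs_r: np.ndarray | None = None,
) -> list[int]:
    """Indices with |r| >= multiplier * mean |r|, or the ranked fallback."""
    if abs_r is None:
        abs_r = np.abs(biserial_vector(matrix, labels))
    threshold = config.relevance_multiplier * abs_r.mean()
    survivors = np.flatnonzero(abs_r >= threshold)
    if survivors.size < config.min_retained:
        k = min(config.min_retained, abs_r.size)
        # stable sort keeps catalog order among exact ties
        order = np.argsort(-abs_r, kind="stable")
        survivors = np.sort(order[:k])
        logger.info(
            "relevance filter kept %d < min_retained; falling back to top %d by |r|",
            int((abs_r >= threshold).sum()), k,
        )
    return [int(i) for i in survivors]


def redundancy_filter(
    matrix: np.ndarray,
    survivors: Sequence[int],
    relevance: np.ndarray,
    config: SelectionConfig = SelectionConfig(),
) -> list[int]:
    """Greedy de-correlation in decreasing |r|; keeps the more relevant member."""
    if not len(survivors):
        raise ValueError("survivors must be non-empty")
    X = np.asarray(matrix, dtype=float)
    order = sorted(survivors, key=lambda j: (-abs(relevance[j]), j))
    kept: list[int] = []
    for j in order:
        xj = X[:, j]
        ok = True
        for i in kept:
            r = np.corrcoef(xj, X[:, i])[0, 1]
            if np.isnan(r):
                r = 0.0
            if abs(r) > config.redundancy_threshold:
                ok = False
                break
        if ok:
            kept.append(j)
    return sorted(kept)


def cv_auc(
    matrix: np.ndarray,
    labels: np.ndarray,
    columns: Sequence[int],
    config: SelectionConfig,
    max_retries: int = 5,
) -> float:
    """Mean AUC of a logistic model over stratified CV folds."""
    X = np.asarray(matrix, dtype=float)[:, list(columns)]
    y = np.asarray(labels, dtype=float)
    for retry in range(max_retries):
        splitter = StratifiedKFold(
            n_splits=config.cv_folds, shuffle=True,
            random_state=config.rng_seed + retry,
        )
        aucs = []
        refold = False
        for train_idx, test_idx in splitter.split(X, y):
            y_tr, y_te = y[train_idx], y[test_idx]
            if np.unique(y_tr).size < 2 or np.unique(y_te).size < 2:
                refold = True
                break
            means, stds = standardize_params(X[train_idx])
            Z_tr = (X[train_idx] - means) / stds
            Z_te = (X[test_idx] - means) / stds
            weights, intercept = fit_logistic_stable(Z_tr, y_tr)
            scores = sigmoid(intercept + Z_te @ weights)
            aucs.append(roc_auc_score(y_te, scores))
        if not refold:
            return float(np.mean(aucs))
        logger.warning("single-class CV fold; refolding (retry %d)", retry + 1)
    raise ValueError("could not build two-class CV folds within retry budget")


def wrapper_select(
    matrix: np.ndarray,
    labels: np.ndarray,
    candidates: Sequence[int],
    config: SelectionConfig = SelectionConfig(),
    outcome: OutcomeLabel | None = None,
    relevance_survivors: Sequence[int] | None = None,
) -> SelectionResult:
    """Single forward scan over rank-ordered candidates, keeping strict
    mean-CV-AUC improvements."""
    candidates = list(candidates)
    if not candidates:
        raise ValueError("candidates must be non-empty")
    selected = [candidates[0]]
    best = cv_auc(matrix, labels, selected, config)
    # the initialization entry starts from chance level (no model yet)
    trace = [TraceEntry(candidates[0], 0.5, best, True)]
    for cand in candidates[1:]:
        auc_after = cv_auc(matrix, labels, selected + [cand], config)
        accepted = auc_after > best
        trace.append(TraceEntry(cand, best, auc_after, accepted))
        if accepted:
            selected.append(cand)
            best = auc_after
    if relevance_survivors is None:
        relevance_survivors = candidates
    return SelectionResult(
        outcome=outcome,
        relevance_survivors=tuple(sorted(relevance_survivors)),
        redundancy_survivors=tuple(sorted(candidates)),
        selected=tuple(selected),
        cv_auc_trace=tuple(trace),
    )


def select_features(
    matrix: np.ndarray,
    labels: np.ndarray,
    config: SelectionConfig = SelectionConfig(),
    outcome: OutcomeLabel | None = None,
) -> SelectionResult:
    """Run relevance -> redundancy -> wrapper on a full feature table."""
    r = biserial_vector(matrix, labels)
    abs_r = np.abs(r)
    relevant = relevance_filter(matrix, labels, config, abs_r=abs_r)
    pruned = redundancy_filter(matrix, relevant, r, config)
    ranked = sorted(pruned, key=lambda j: (-abs_r[j], j))
    return wrapper_select(
        matrix, labels, ranked, config, outcome=outcome,
        relevance_survivors=relevant,
    )
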