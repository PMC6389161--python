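"""End-to-end orchestration: feature table + labels -> four fitted models.

Thin glue shared by the command-line interface and scripted analyses; all
science lives in the stage modules.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .models import OutcomeModel, predict_propensity, train_outcome_model
from .outcomes import OUTCOMES, OutcomeLabel
from .selection import SelectionConfig, SelectionResult, select_features

logger = logging.getLogger(__name__)


def one_vs_rest_labels(
    ids: Sequence[str], labels: Mapping[str, OutcomeLabel], positive: OutcomeLabel
) -> np.ndarray:
    missing = [i for i in ids if i not in labels]
    if missing:
        raise ValueError(f"no outcome label for id(s): {missing[:5]}")
    return np.array([1 if labels[i] == positive else 0 for i in ids])


def train_all_outcomes(
    features: pd.DataFrame,
    labels: Mapping[str, OutcomeLabel],
    selection_config: SelectionConfig = SelectionConfig(),
) -> tuple[dict[OutcomeLabel, OutcomeModel], dict[OutcomeLabel, SelectionResult]]:
    """Select features and fit one logistic model per outcome.

    ``features`` is the (proteins x catalog) table from
    :func:`xtalfate.features.extract_matrix`; ``labels`` maps protein id to
    its outcome. Each outcome is treated one-vs-rest.
    """
    matrix = features.to_numpy(dtype=float)
    names = list(features.columns)
    models: dict[OutcomeLabel, OutcomeModel] = {}
    selections: dict[OutcomeLabel, SelectionResult] = {}
    for outcome in OUTCOMES:
        y = one_vs_rest_labels(features.index, labels, outcome)
        if np.unique(y).size < 2:
            raise ValueError(f"outcome {outcome.value} has a single class")
        sel = select_features(matrix, y, selection_config, outcome=outcome)
        logger.info(
            "%s: %d relevance -> %d redundancy -> %d selected",
            outcome.value,
            len(sel.relevance_survivors),
            len(sel.redundancy_survivors),
            len(sel.selected),
        )
        cols = list(sel.selected)
        models[outcome] = train_outcome_model(
            matrix[:, cols],
            y,
            outcome,
            feature_indices=cols,
            feature_names=[names[j] for j in cols],
        )
        selections[outcome] = sel
    return models, selections


def heldout_outcome_aucs(
    n_per_class: int = 400,
    effect_size: float = 0.5,
    seed: int = 0,
    test_fraction: float = 0.5,
) -> dict[OutcomeLabel, float]:
    """Train on a class-stratified split of a synthetic dataset and report
    held-out one-vs-rest AUC per outcome.

    This is the package's standard self-check: with ``effect_size`` 0 the
    classes are exchangeable and every AUC should sit at chance level;
    with a strong effect all four outcomes become separable.
    """
    from .evaluation import roc_auc
    from .features import extract_matrix
    from .synthetic import SyntheticConfig, generate_dataset

    dataset = generate_dataset(
        SyntheticConfig(
            n_per_class={o: n_per_class for o in OUTCOMES},
            effect_size=effect_size,
            rng_seed=seed,
        )
    )
    rng = np.random.default_rng(seed + 1)
    test_ids: set[str] = set()
    for outcome in OUTCOMES:
        ids = [r.id for r in dataset.records if dataset.labels[r.id] == outcome]
        n_test = int(round(test_fraction * len(ids)))
        test_ids.update(rng.choice(ids, size=n_test, replace=False))
    train_recs = [r for r in dataset.records if r.id not in test_ids]
    test_recs = [r for r in dataset.records if r.id in test_ids]
    df_train = extract_matrix(train_recs)
    df_test = extract_matrix(test_recs)
    models, _ = train_all_outcomes(
        df_train, dataset.labels, SelectionConfig(rng_seed=seed + 2)
    )
    aucs: dict[OutcomeLabel, float] = {}
    test_matrix = df_test.to_numpy(dtype=float)
    for outcome in OUTCOMES:
        y = one_vs_rest_labels(df_test.index, dataset.labels, outcome)
        scores = [predict_propensity(models[outcome], row) for row in test_matrix]
        aucs[outcome] = roc_auc(scores, y)
    return aucs
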