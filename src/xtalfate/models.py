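"""Per-outcome logistic-regression models, propensities and confidence tiers.

One independent binary model is trained per pipeline outcome (MF, PF, CF,
CR) on its selected feature subset. Features are standardized, the model is
fitted by iteratively reweighted least squares (plain maximum likelihood; a
tiny ridge is applied only when the fit separates), and confidence tiers are
calibrated from the empirical 20th/80th percentiles of the training
propensities: the lowest and highest 20% of training propensities define the
"low" and "high" tiers, everything between is "medium". A protein's overall
call is the outcome with the highest propensity.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .features import FeatureCatalog, FeatureVector, build_catalog, extract_all
from .outcomes import OUTCOMES, OutcomeLabel
from .sequence_io import ProteinRecord

logger = logging.getLogger(__name__)

BUNDLE_FORMAT_VERSION = 1
_IRLS_TOL = 1e-8
_IRLS_MAX_ITER = 100
_SEPARATION_RIDGE = 1e-4

CONF_LOW, CONF_MEDIUM, CONF_HIGH = "low", "medium", "high"


def sigmoid(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    ridge: float = 0.0,
    tol: float = _IRLS_TOL,
    max_iter: int = _IRLS_MAX_ITER,
) -> tuple[np.ndarray, float, bool]:
    """Maximum-likelihood logistic fit by Newton/IRLS from a zero start.

    Returns (weights, intercept, converged). The optional ridge penalty
    (on all coefficients including the intercept's slope terms, not the
    intercept itself) stabilizes separated data.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    Xd = np.column_stack([np.ones(n), X])
    beta = np.zeros(k + 1)
    penalty = np.zeros(k + 1)
    penalty[1:] = ridge
    converged = False
    for _ in range(max_iter):
        p = sigmoid(Xd @ beta)
        w = p * (1.0 - p)
        # guard against exactly saturated probabilities
        w = np.maximum(w, 1e-12)
        hess = Xd.T @ (Xd * w[:, None]) + np.diag(penalty)
        grad = Xd.T @ (y - p) - penalty * beta
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if not np.all(np.isfinite(beta)):
            converged = False
            break
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    return beta[1:], float(beta[0]), converged


def fit_logistic_stable(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """ML fit; falls back to a ridge-stabilized fit on (quasi-)separation."""
    weights, intercept, converged = fit_logistic(X, y)
    if converged and np.all(np.isfinite(weights)):
        return weights, intercept
    logger.warning(
        "logistic fit did not converge (possible separation); "
        "refitting with ridge %g", _SEPARATION_RIDGE,
    )
    weights, intercept, _ = fit_logistic(X, y, ridge=_SEPARATION_RIDGE)
    return weights, intercept


def standardize_params(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column (mean, std); constant columns get std 1."""
    means = X.mean(axis=0)
    stds = X.std(axis=0)
    stds = np.where(stds == 0.0, 1.0, stds)
    return means, stds


@dataclasses.dataclass(frozen=True)
class OutcomeModel:
    """A fitted logistic model for one outcome, with tier calibration."""

    outcome: OutcomeLabel
    feature_indices: tuple[int, ...]
    feature_names: tuple[str, ...]
    weights: np.ndarray
    intercept: float
    means: np.ndarray
    stds: np.ndarray
    confidence_low: float
    confidence_high: float

    def __post_init__(self) -> None:
        if not (
            len(self.feature_indices)
            == len(self.feature_names)
            == self.weights.size
            == self.means.size
            == self.stds.size
        ):
            raise ValueError("model field lengths must agree")
        if not 0.0 <= self.confidence_low <= self.confidence_high <= 1.0:
            raise ValueError("confidence thresholds must be ordered in [0, 1]")


@dataclasses.dataclass(frozen=True)
class PredictionReport:
    """Four propensities, the overall call and per-outcome confidence tiers."""

    protein_id: str
    propensities: Mapping[OutcomeLabel, float]
    overall: OutcomeLabel
    confidence: Mapping[OutcomeLabel, str]


def train_outcome_model(
    X: np.ndarray,
    y: np.ndarray,
    outcome: OutcomeLabel,
    feature_indices: Sequence[int] | None = None,
    feature_names: Sequence[str] | None = None,
    return_propensities: bool = False,
):
    """Fit one outcome model on an (n x k) feature table with binary labels.

    ``X`` holds only the k selected features (columns in the order of
    ``feature_indices``). Confidence thresholds are the 20th/80th
    linear-interpolation percentiles of the fitted training propensities.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be n x k aligned with labels")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training labels contain a single class")
    if not np.all(np.isfinite(X)):
        raise ValueError("training features contain non-finite values")
    k = X.shape[1]
    if feature_indices is None:
        feature_indices = tuple(range(k))
    if feature_names is None:
        feature_names = tuple(f"f{i}" for i in feature_indices)
    means, stds = standardize_params(X)
    Z = (X - means) / stds
    weights, intercept = fit_logistic_stable(Z, y)
    propensities = sigmoid(intercept + Z @ weights)
    low, high = np.percentile(propensities, [20.0, 80.0])
    model = OutcomeModel(
        outcome=outcome,
        feature_indices=tuple(int(i) for i in feature_indices),
        feature_names=tuple(feature_names),
        weights=np.asarray(weights, dtype=float),
        intercept=float(intercept),
        means=np.asarray(means, dtype=float),
        stds=np.asarray(stds, dtype=float),
        confidence_low=float(low),
        confidence_high=float(high),
    )
    if return_propensities:
        return model, propensities
    return model


def _model_columns(model: OutcomeModel, vector) -> np.ndarray:
    if isinstance(vector, FeatureVector):
        values = vector.values
        name = vector.protein_id
    else:
        values = np.asarray(vector, dtype=float)
        name = "<vector>"
    cols = values[list(model.feature_indices)]
    if not np.all(np.isfinite(cols)):
        bad = model.feature_names[int(np.flatnonzero(~np.isfinite(cols))[0])]
        raise ValueError(f"non-finite feature {bad!r} for {name}")
    return cols


def predict_propensity(model: OutcomeModel, vector) -> float:
    """Propensity in (0, 1) for one protein's (full-catalog) feature vector."""
    cols = _model_columns(model, vector)
    z = (cols - model.means) / model.stds
    return float(sigmoid(model.intercept + z @ model.weights))


def assign_confidence(model: OutcomeModel, propensity: float) -> str:
    """Tier by strict comparison to the calibrated 20th/80th percentiles."""
    if propensity < model.confidence_low:
        return CONF_LOW
    if propensity > model.confidence_high:
        return CONF_HIGH
    return CONF_MEDIUM


def predict_all(
    models: Mapping[OutcomeLabel, OutcomeModel],
    record: ProteinRecord,
    catalog: FeatureCatalog | None = None,
) -> PredictionReport:
    """Extract features once and produce the full four-outcome report.

    The overall call is the highest propensity; exact ties go to the
    outcome further along the pipeline (CR last).
    """
    missing = [o.value for o in OUTCOMES if o not in models]
    if missing:
        raise ValueError(f"missing model(s) for outcome(s): {missing}")
    if catalog is None:
        catalog = build_catalog()
    vector = extract_all(record, catalog)
    propensities = {o: predict_propensity(models[o], vector) for o in OUTCOMES}
    overall = max(OUTCOMES, key=lambda o: (propensities[o], o.pipeline_rank))
    confidence = {o: assign_confidence(models[o], propensities[o]) for o in OUTCOMES}
    return PredictionReport(record.id, propensities, overall, confidence)


def report_from_vector(
    models: Mapping[OutcomeLabel, OutcomeModel], vector: FeatureVector
) -> PredictionReport:
    """Like :func:`predict_all` but from an already-extracted vector."""
    propensities = {o: predict_propensity(models[o], vector) for o in OUTCOMES}
    overall = max(OUTCOMES, key=lambda o: (propensities[o], o.pipeline_rank))
    confidence = {o: assign_confidence(models[o], propensities[o]) for o in OUTCOMES}
    return PredictionReport(vector.protein_id, propensities, overall, confidence)


# ---------------------------------------------------------------------------
# plain-text model bundles

def save_bundle(models: Mapping[OutcomeLabel, OutcomeModel], directory) -> None:
    """Write one JSON text file per outcome plus a manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format_version": BUNDLE_FORMAT_VERSION,
        "outcomes": [o.value for o in OUTCOMES if o in models],
    }
    for outcome, model in models.items():
        payload = {
            "format_version": BUNDLE_FORMAT_VERSION,
            "outcome": outcome.value,
            "feature_indices": list(model.feature_indices),
            "feature_names": list(model.feature_names),
            "weights": model.weights.tolist(),
            "intercept": model.intercept,
            "means": model.means.tolist(),
            "stds": model.stds.tolist(),
            "confidence_low": model.confidence_low,
            "confidence_high": model.confidence_high,
        }
        (directory / f"model_{outcome.value}.json").write_text(
            json.dumps(payload, indent=1)
        )
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_bundle(directory) -> dict[OutcomeLabel, OutcomeModel]:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    if manifest["format_version"] != BUNDLE_FORMAT_VERSION:
        raise ValueError(
            f"unsupported bundle format version {manifest['format_version']}"
        )
    models: dict[OutcomeLabel, OutcomeModel] = {}
    for value in manifest["outcomes"]:
        payload = json.loads((directory / f"model_{value}.json").read_text())
        outcome = OutcomeLabel(payload["outcome"])
        models[outcome] = OutcomeModel(
            outcome=outcome,
            feature_indices=tuple(payload["feature_indices"]),
            feature_names=tuple(payload["feature_names"]),
            weights=np.asarray(payload["weights"], dtype=float),
            intercept=float(payload["intercept"]),
            means=np.asarray(payload["means"], dtype=float),
            stds=np.asarray(payload["stds"], dtype=float),
            confidence_low=float(payload["confidence_low"]),
            confidence_high=float(payload["confidence_high"]),
        )
    return models
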