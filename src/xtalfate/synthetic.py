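"""Synthetic labeled data with controllable class structure.

Two generators support end-to-end testing without any external download:

* :func:`generate_dataset` emits protein sequences whose residue
  composition is shifted per outcome class along fixed direction vectors
  (loosely motivated by published crystallizability trends: successful
  targets enriched in small/ordered residues, production failures in
  hydrophobics/aromatics, purification failures in charged residues,
  crystallization failures in polar low-complexity-prone residues). The
  ``effect_size`` knob scales those shifts; 0 gives identically distributed
  classes, so any downstream discrimination is spurious.
* :func:`generate_feature_table` emits a numeric table with a known
  logistic generative model, for selection-recovery and parameter-recovery
  tests.

Both are fully reproducible from their seed.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Mapping

import numpy as np

from .outcomes import OUTCOMES, OutcomeLabel
from .sequence_io import STANDARD_AA, ProteinRecord, write_fasta
from .annotation import write_labels

logger = logging.getLogger(__name__)

_AA = np.array(list(STANDARD_AA))
MIN_LENGTH, MAX_LENGTH = 30, 2000


def _direction(positive: str, scale: float = 0.3) -> np.ndarray:
    """Zero-sum composition shift: +scale spread over `positive` residues."""
    d = np.full(20, -scale / (20 - len(positive)))
    for aa in positive:
        d[STANDARD_AA.index(aa)] = scale / len(positive)
    return d


#: Fixed per-class composition-shift directions (zero-sum over the alphabet).
CLASS_DIRECTIONS: dict[OutcomeLabel, np.ndarray] = {
    OutcomeLabel.MF: _direction("FILMVWY"),   # hydrophobic/aromatic
    OutcomeLabel.PF: _direction("DEKR"),      # charged
    OutcomeLabel.CF: _direction("NPQS"),      # polar, repeat/low-complexity prone
    OutcomeLabel.CR: _direction("ADGSTV"),    # small/ordered
}


@dataclasses.dataclass(frozen=True)
class SyntheticConfig:
    n_per_class: Mapping[OutcomeLabel, int] = dataclasses.field(
        default_factory=lambda: {o: 400 for o in OUTCOMES}
    )
    median_length: float = 300.0
    length_dispersion: float = 0.4  # sigma of log length
    effect_size: float = 0.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.n_per_class.values()):
            raise ValueError("class counts must be >= 0")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")


def class_composition(label: OutcomeLabel, effect_size: float) -> np.ndarray:
    """Residue probabilities for one class; clipped and renormalized."""
    p = np.full(20, 0.05) + effect_size * CLASS_DIRECTIONS[label]
    if np.any(p <= 0.0):
        logger.warning(
            "effect_size %.3g drives probabilities negative for %s; clipping",
            effect_size, label.value,
        )
        p = np.clip(p, 1e-4, None)
    return p / p.sum()


@dataclasses.dataclass(frozen=True)
class LabeledSequences:
    records: tuple[ProteinRecord, ...]
    labels: Mapping[str, OutcomeLabel]

    def write(self, fasta_path, labels_path) -> None:
        write_fasta(self.records, fasta_path)
        write_labels(dict(self.labels), labels_path)

    def label_array(self, positive: OutcomeLabel) -> np.ndarray:
        """0/1 labels (one-vs-rest) aligned with ``records`` order."""
        return np.array(
            [1 if self.labels[r.id] == positive else 0 for r in self.records]
        )


def generate_dataset(config: SyntheticConfig = SyntheticConfig()) -> LabeledSequences:
    """Draw labeled sequences residue-by-residue from class compositions."""
    active = [o for o in OUTCOMES if config.n_per_class.get(o, 0) > 0]
    if len(active) < 2:
        raise ValueError("need at least two classes with positive counts")
    rng = np.random.default_rng(config.rng_seed)
    mu = math.log(config.median_length)
    records: list[ProteinRecord] = []
    labels: dict[str, OutcomeLabel] = {}
    for label in active:
        comp = class_composition(label, config.effect_size)
        for i in range(config.n_per_class[label]):
            length = int(
                np.clip(
                    round(rng.lognormal(mu, config.length_dispersion)),
                    MIN_LENGTH,
                    MAX_LENGTH,
                )
            )
            seq = "".join(rng.choice(_AA, size=length, p=comp))
            rec = ProteinRecord(f"{label.value}_{i:04d}", seq)
            records.append(rec)
            labels[rec.id] = label
    return LabeledSequences(tuple(records), labels)


def generate_feature_table(
    n: int,
    p: int,
    k_informative: int,
    weights=None,
    rng_seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Numeric table with a known logistic generative model.

    The first ``k_informative`` standard-normal columns enter a logistic
    label model with the given weights (default 2.0 each); the remaining
    columns are independent noise.
    """
    if k_informative > p:
        raise ValueError("k_informative must be <= p")
    rng = np.random.default_rng(rng_seed)
    X = rng.standard_normal((n, p))
    if k_informative:
        w = (
            np.full(k_informative, 2.0)
            if weights is None
            else np.asarray(weights, dtype=float)
        )
        if w.size != k_informative:
            raise ValueError("weights must have length k_informative")
        logits = X[:, :k_informative] @ w
    else:
        logits = np.zeros(n)
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-logits))).astype(int)
    return X, y
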