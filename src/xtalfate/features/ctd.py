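"""Composition/Transition/Distribution (CTD) features over 3-class alphabets.

Each of the seven physicochemical properties recodes the sequence into three
classes and contributes 48 features: class composition (3), normalized
between-class transition frequencies (3), positional distribution of each
class (15), and run/segment characteristics of each class (27). With seven
properties the block totals 336 features.
"""

from __future__ import annotations

import math
from functools import lru_cache
from typing import Sequence

import numpy as np

from .composition import encode
from .tables import PropertyAlphabet, load_property_alphabets

_DIST_FRACTIONS = (0.0, 0.25, 0.50, 0.75, 1.0)
_DIST_TAGS = ("first", "q25", "q50", "q75", "last")
_SEG_TAGS = (
    "run_count",
    "longest_run",
    "shortest_run",
    "mean_run",
    "coverage",
    "runs_ge2",
    "runs_ge3",
    "first_pos",
    "last_pos",
)


def _runs(mask: np.ndarray) -> list[int]:
    """Lengths of maximal runs of True, in order of occurrence."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    return list(edges[1::2] - edges[0::2])


def _distribution(positions: np.ndarray, length: int) -> list[float]:
    """Normalized position of the 1st/25%/50%/75%/100% class occurrence."""
    n = positions.size
    if n == 0:
        return [0.0] * len(_DIST_FRACTIONS)
    out = []
    for frac in _DIST_FRACTIONS:
        k = max(1, math.ceil(frac * n))  # k-th occurrence, 1-based
        out.append((positions[k - 1] + 1) / length)
    return out


def ctd_features(
    sequence: str, alphabets: Sequence[PropertyAlphabet] | None = None
) -> np.ndarray:
    """The 336 CTD features (48 per property alphabet, 7 alphabets)."""
    if alphabets is None:
        alphabets = load_property_alphabets()
    codes = encode(sequence)
    length = len(sequence)
    out: list[float] = []
    for alphabet in alphabets:
        cls = alphabet.class_of()[codes]
        # composition
        comp = np.bincount(cls, minlength=3) / length
        out.extend(comp)
        # transitions between unordered class pairs, over L-1 adjacent pairs
        a, b = cls[:-1], cls[1:]
        for ci, cj in ((0, 1), (0, 2), (1, 2)):
            n_trans = np.count_nonzero(
                ((a == ci) & (b == cj)) | ((a == cj) & (b == ci))
            )
            out.append(n_trans / (length - 1) if length > 1 else 0.0)
        # distribution
        for ci in range(3):
            out.extend(_distribution(np.flatnonzero(cls == ci), length))
        # segment characteristics
        for ci in range(3):
            mask = cls == ci
            runs = _runs(mask)
            if not runs:
                out.extend([0.0] * len(_SEG_TAGS))
                continue
            positions = np.flatnonzero(mask)
            out.extend(
                [
                    len(runs) / length,
                    max(runs) / length,
                    min(runs) / length,
                    (sum(runs) / len(runs)) / length,
                    positions.size / length,
                    sum(r >= 2 for r in runs) / length,
                    sum(r >= 3 for r in runs) / length,
                    (positions[0] + 1) / length,
                    (positions[-1] + 1) / length,
                ]
            )
    return np.asarray(out, dtype=float)


@lru_cache(maxsize=1)
def ctd_names() -> tuple[str, ...]:
    names: list[str] = []
    for alphabet in load_property_alphabets():
        prefix = f"CTD_{alphabet.name}"
        names += [f"{prefix}_comp_c{i + 1}" for i in range(3)]
        names += [f"{prefix}_trans_c{i + 1}c{j + 1}" for i, j in ((0, 1), (0, 2), (1, 2))]
        for ci in range(3):
            names += [f"{prefix}_dist_c{ci + 1}_{t}" for t in _DIST_TAGS]
        for ci in range(3):
            names += [f"{prefix}_seg_c{ci + 1}_{t}" for t in _SEG_TAGS]
    return tuple(names)
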