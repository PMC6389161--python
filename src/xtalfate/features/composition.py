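"""Amino-acid and dipeptide composition (420 features)."""

from __future__ import annotations

import numpy as np

from ..sequence_io import STANDARD_AA
from .tables import AA_INDEX


def encode(sequence: str) -> np.ndarray:
    """Sequence -> integer codes 0..19 (alphabetical one-letter order)."""
    return np.fromiter(
        (AA_INDEX[aa] for aa in sequence), dtype=np.int64, count=len(sequence)
    )


def aa_composition(sequence: str) -> np.ndarray:
    """Fractional composition of the 20 amino acids, alphabetical order."""
    codes = encode(sequence)
    return np.bincount(codes, minlength=20) / len(sequence)


def dipeptide_composition(sequence: str) -> np.ndarray:
    """Fractions of the 400 adjacent residue pairs among the L-1 pairs.

    Order: first residue alphabetical, then second (AA, AC, ..., YY).
    """
    if len(sequence) < 2:
        raise ValueError("dipeptide composition requires length >= 2")
    codes = encode(sequence)
    pair_codes = codes[:-1] * 20 + codes[1:]
    return np.bincount(pair_codes, minlength=400) / (len(sequence) - 1)


AAC_NAMES = [f"AAC_{aa}" for aa in STANDARD_AA]
DPC_NAMES = [f"DPC_{a}{b}" for a in STANDARD_AA for b in STANDARD_AA]
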