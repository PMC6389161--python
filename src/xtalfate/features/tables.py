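"""Loaders for the plain-text constant tables bundled with the package.

Three tables live in ``features/data``:

* ``property_alphabets.tsv`` — seven 3-class residue partitions for CTD
  encoding;
* ``base_scales.tsv`` + ``synthetic_scales.tsv`` — 64 per-residue numeric
  scales (16 classical published scales plus 48 synthetic seeded
  combinations of them; the synthetic rows are stand-ins for a larger
  curated collection and are labelled as such in their file);
* ``pka_set.tsv`` — ionizable-group pKa values (EMBOSS set) for charge/pI.
"""

from __future__ import annotations

import dataclasses
from functools import lru_cache
from importlib import resources

import numpy as np

from ..sequence_io import STANDARD_AA

AA_INDEX = {aa: i for i, aa in enumerate(STANDARD_AA)}


def _data_lines(filename: str) -> list[list[str]]:
    text = (resources.files("xtalfate.features") / "data" / filename).read_text()
    rows = [
        line.rstrip("\n").split("\t")
        for line in text.splitlines()
        if line and not line.startswith("#")
    ]
    return rows


@dataclasses.dataclass(frozen=True)
class PropertyAlphabet:
    """A named partition of the 20 amino acids into three classes."""

    name: str
    classes: tuple[str, str, str]

    def __post_init__(self) -> None:
        joined = "".join(self.classes)
        if len(joined) != 20 or set(joined) != set(STANDARD_AA):
            raise ValueError(
                f"alphabet {self.name!r} is not a 3-class partition of the "
                f"20 standard amino acids"
            )

    def class_of(self) -> np.ndarray:
        """Residue index -> class index (0/1/2), aligned to STANDARD_AA."""
        out = np.empty(20, dtype=np.int8)
        for ci, members in enumerate(self.classes):
            for aa in members:
                out[AA_INDEX[aa]] = ci
        return out


@dataclasses.dataclass(frozen=True)
class ResidueIndexTable:
    """A named per-residue numeric scale (20 values, alphabetical order)."""

    name: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) != 20:
            raise ValueError(f"scale {self.name!r} must have 20 values")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


@lru_cache(maxsize=1)
def load_property_alphabets() -> tuple[PropertyAlphabet, ...]:
    rows = _data_lines("property_alphabets.tsv")
    assert rows[0] == ["name", "class1", "class2", "class3"]
    alphabets = tuple(
        PropertyAlphabet(r[0], (r[1], r[2], r[3])) for r in rows[1:]
    )
    if len(alphabets) != 7:
        raise ValueError("expected exactly 7 property alphabets")
    return alphabets


def _load_scale_file(filename: str) -> list[ResidueIndexTable]:
    rows = _data_lines(filename)
    header = rows[0]
    assert header[0] == "name" and "".join(header[1:]) == STANDARD_AA
    return [
        ResidueIndexTable(r[0], tuple(float(v) for v in r[1:])) for r in rows[1:]
    ]


@lru_cache(maxsize=1)
def load_residue_scales() -> tuple[ResidueIndexTable, ...]:
    """The bundled 64-scale set: 16 classical + 48 synthetic."""
    scales = _load_scale_file("base_scales.tsv") + _load_scale_file(
        "synthetic_scales.tsv"
    )
    if len(scales) != 64:
        raise ValueError(f"expected 64 residue scales, found {len(scales)}")
    names = [s.name for s in scales]
    if len(set(names)) != 64:
        raise ValueError("residue scale names must be unique")
    return tuple(scales)


@lru_cache(maxsize=1)
def load_pka_set() -> dict[str, tuple[float, int]]:
    """Group -> (pKa, sign); sign +1 for basic groups, -1 for acidic."""
    rows = _data_lines("pka_set.tsv")
    assert rows[0] == ["group", "pka", "sign"]
    return {r[0]: (float(r[1]), +1 if r[2] == "+" else -1) for r in rows[1:]}
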