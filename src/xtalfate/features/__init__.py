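"""The ordered 1276-dimension sequence feature space.

Five groups: amino-acid + dipeptide composition (AAC, 420), three-class
physicochemical CTD descriptors (CLUSTER, 336), residue-scale profile
statistics (AAPHYS, 448), whole-protein physicochemical indices
(PROTPHYS, 4) and disorder/low-complexity profile summaries (CXDIS, 68).
Group sizes are asserted at catalog construction and the ordering is fixed
across runs and platforms.
"""

from __future__ import annotations

import dataclasses
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ..sequence_io import ProteinRecord
from .composition import AAC_NAMES, DPC_NAMES, aa_composition, dipeptide_composition
from .ctd import ctd_features, ctd_names
from .physchem import PHYSCHEM_NAMES, global_physchem
from .profiles import (
    PROFILE_STAT_NAMES,
    disorder_profile,
    low_complexity_mask,
    profile_summary34,
)
from .scales import aaindex_features, scale_feature_names
from .tables import (
    PropertyAlphabet,
    ResidueIndexTable,
    load_property_alphabets,
    load_residue_scales,
)

GROUP_SIZES = {"AAC": 420, "CLUSTER": 336, "AAPHYS": 448, "PROTPHYS": 4, "CXDIS": 68}
TOTAL_FEATURES = 1276


@dataclasses.dataclass(frozen=True)
class FeatureCatalog:
    """Ordered (name, group) entries defining the feature space."""

    names: tuple[str, ...]
    groups: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.groups):
            raise ValueError("names and groups must align")
        if len(self.names) != TOTAL_FEATURES:
            raise ValueError(f"catalog must have {TOTAL_FEATURES} entries")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")
        counts: dict[str, int] = {}
        for g in self.groups:
            counts[g] = counts.get(g, 0) + 1
        if counts != GROUP_SIZES:
            raise ValueError(f"group sizes {counts} != required {GROUP_SIZES}")

    def __len__(self) -> int:
        return len(self.names)

    def group_indices(self, group: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.groups) == group)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("name\tgroup\n")
            for name, group in zip(self.names, self.groups):
                fh.write(f"{name}\t{group}\n")


@dataclasses.dataclass(frozen=True)
class FeatureVector:
    """One protein's coordinates in the catalog's feature space."""

    protein_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != (TOTAL_FEATURES,):
            raise ValueError("feature vector must have catalog length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite feature values for {self.protein_id!r}")


@lru_cache(maxsize=1)
def build_catalog() -> FeatureCatalog:
    names: list[str] = []
    groups: list[str] = []

    def add(block_names: Iterable[str], group: str) -> None:
        for n in block_names:
            names.append(n)
            groups.append(group)

    add(AAC_NAMES, "AAC")
    add(DPC_NAMES, "AAC")
    add(ctd_names(), "CLUSTER")
    add(scale_feature_names(), "AAPHYS")
    add(PHYSCHEM_NAMES, "PROTPHYS")
    add((f"DIS_{s}" for s in PROFILE_STAT_NAMES), "CXDIS")
    add((f"LC_{s}" for s in PROFILE_STAT_NAMES), "CXDIS")
    return FeatureCatalog(tuple(names), tuple(groups))


def extract_all(
    record: ProteinRecord, catalog: FeatureCatalog | None = None
) -> FeatureVector:
    """Extract the full, deterministic 1276-feature vector for one protein."""
    if catalog is None:
        catalog = build_catalog()
    seq = record.sequence
    length = len(seq)
    values = np.concatenate(
        [
            aa_composition(seq),
            dipeptide_composition(seq),
            ctd_features(seq),
            aaindex_features(seq),
            global_physchem(seq),
            profile_summary34(disorder_profile(seq), length),
            profile_summary34(low_complexity_mask(seq).astype(float), length),
        ]
    )
    return FeatureVector(record.id, values)


def extract_matrix(
    records: Sequence[ProteinRecord], catalog: FeatureCatalog | None = None
) -> pd.DataFrame:
    """Feature table (records x catalog), indexed by protein id."""
    if catalog is None:
        catalog = build_catalog()
    rows = [extract_all(rec, catalog).values for rec in records]
    return pd.DataFrame(
        np.vstack(rows) if rows else np.empty((0, len(catalog))),
        index=[rec.id for rec in records],
        columns=list(catalog.names),
    )


__all__ = [
    "FeatureCatalog",
    "FeatureVector",
    "GROUP_SIZES",
    "TOTAL_FEATURES",
    "PropertyAlphabet",
    "ResidueIndexTable",
    "aa_composition",
    "dipeptide_composition",
    "ctd_features",
    "aaindex_features",
    "global_physchem",
    "disorder_profile",
    "low_complexity_mask",
    "profile_summary34",
    "build_catalog",
    "extract_all",
    "extract_matrix",
    "load_property_alphabets",
    "load_residue_scales",
]
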