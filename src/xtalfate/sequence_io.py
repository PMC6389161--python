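"""FASTA input with validation, and tabular prediction output.

Sequences are validated against the 20-letter standard amino-acid alphabet
and a minimum length (default 30 residues — shorter chains are peptides and
outside the predictor's domain). Invalid records are rejected individually
with machine-readable reasons, mirroring a batch server that processes what
it can.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .outcomes import OUTCOMES

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
_STANDARD_SET = frozenset(STANDARD_AA)

#: rejection reasons, in check order
REASON_EMPTY = "empty-sequence"
REASON_TOO_SHORT = "too-short"
REASON_NON_STANDARD = "non-standard-residue"
REASON_DUPLICATE = "duplicate-id"


class EmptyBatchError(ValueError):
    """A parseable FASTA file yielded zero valid records."""


class BatchValidationError(ValueError):
    """Raised under the reject-batch policy when any record is invalid."""


@dataclasses.dataclass(frozen=True)
class ProteinRecord:
    """One validated protein: FASTA id (up to first whitespace) + sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if not _STANDARD_SET.issuperset(self.sequence):
            bad = sorted(set(self.sequence) - _STANDARD_SET)
            raise ValueError(f"non-standard residues in {self.id!r}: {bad}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclasses.dataclass(frozen=True)
class Rejection:
    id: str
    reason: str


@dataclasses.dataclass(frozen=True)
class ValidationConfig:
    min_length: int = 30
    on_invalid: str = "reject-record"  # or "reject-batch"

    def __post_init__(self) -> None:
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if self.on_invalid not in ("reject-record", "reject-batch"):
            raise ValueError(f"unknown on_invalid policy: {self.on_invalid!r}")


def _validate(raw_id: str, raw_seq: str, seen: set, config: ValidationConfig):
    """Return (record, None) or (None, Rejection); upper-cases before checks."""
    seq = raw_seq.upper()
    if not seq:
        return None, Rejection(raw_id, REASON_EMPTY)
    if raw_id in seen:
        return None, Rejection(raw_id, REASON_DUPLICATE)
    if not _STANDARD_SET.issuperset(seq):
        return None, Rejection(raw_id, REASON_NON_STANDARD)
    if len(seq) < config.min_length:
        return None, Rejection(raw_id, REASON_TOO_SHORT)
    return ProteinRecord(raw_id, seq), None


def read_fasta(
    path, config: ValidationConfig = ValidationConfig()
) -> tuple[list[ProteinRecord], list[Rejection]]:
    """Read and validate a multi-record FASTA file.

    Returns (valid records in input order, rejections with reasons).
    Raises OSError for unreadable files and :class:`EmptyBatchError` when the
    file parses but contains no valid record.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    rejections: list[Rejection] = []
    seen: set[str] = set()
    with open(path) as handle:
        for entry in SeqIO.parse(handle, "fasta"):
            rec, rej = _validate(entry.id, str(entry.seq), seen, config)
            if rec is not None:
                seen.add(rec.id)
                records.append(rec)
            else:
                rejections.append(rej)
    if rejections and config.on_invalid == "reject-batch":
        raise BatchValidationError(
            f"{len(rejections)} invalid record(s), first: "
            f"{rejections[0].id} ({rejections[0].reason})"
        )
    if not records:
        raise EmptyBatchError(f"no valid records in {path}")
    return records, rejections


def write_fasta(records: Iterable[ProteinRecord], path, width: int = 60) -> None:
    """Write records as wrapped FASTA."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


_PRED_COLUMNS = (
    ["id"]
    + [f"p_{o.value}" for o in OUTCOMES]
    + ["overall"]
    + [f"conf_{o.value}" for o in OUTCOMES]
)


def write_predictions(reports: Sequence, path) -> None:
    """Write prediction reports as a TSV table (propensities at 6 decimals).

    Columns: id, p_MF, p_PF, p_CF, p_CR, overall, conf_MF..conf_CR.
    Raises ValueError on an empty report list (no file is created).
    """
    if not reports:
        raise ValueError("cannot write an empty prediction table")
    with open(path, "w") as fh:
        fh.write("\t".join(_PRED_COLUMNS) + "\n")
        for rep in reports:
            row = [rep.protein_id]
            row += [f"{rep.propensities[o]:.6f}" for o in OUTCOMES]
            row.append(rep.overall.value)
            row += [rep.confidence[o] for o in OUTCOMES]
            fh.write("\t".join(row) + "\n")


def read_predictions(path) -> list[dict]:
    """Parse a prediction TSV back into plain dicts (round-trip helper)."""
    import csv

    from .outcomes import OutcomeLabel

    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames != _PRED_COLUMNS:
            raise ValueError(f"unexpected prediction-table header in {path}")
        out = []
        for row in reader:
            out.append(
                {
                    "protein_id": row["id"],
                    "propensities": {
                        o: float(row[f"p_{o.value}"]) for o in OUTCOMES
                    },
                    "overall": OutcomeLabel(row["overall"]),
                    "confidence": {o: row[f"conf_{o.value}"] for o in OUTCOMES},
                }
            )
    return out
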