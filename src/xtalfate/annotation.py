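"""Outcome labels from crystallization-trial status records.

Structural-genomics registries (PepcDB/TargetTrack lineage) record a free-
text "stop status" or "current status" per trial. A fixed, editable table
maps the recognized status strings to the four outcomes; unrecognized
statuses are left unmapped rather than erroring. When one sequence has
several trials, the label of the trial that progressed farthest along the
pipeline wins (a protein that reached purification evidently did not fail
material production).
"""

from __future__ import annotations

import dataclasses
import re
from typing import Iterable, Sequence

from .outcomes import OutcomeLabel

STATUS_KIND_STOP = "stop"
STATUS_KIND_CURRENT = "current"

#: stop-status string -> outcome (normalized: lower case, single spaces)
STOP_STATUS_MAP: dict[str, OutcomeLabel] = {
    "sequencing failed": OutcomeLabel.MF,
    "cloning failed": OutcomeLabel.MF,
    "expression failed": OutcomeLabel.MF,
    "purification failed": OutcomeLabel.PF,
    "crystallization failed": OutcomeLabel.CF,
    "poor diffraction": OutcomeLabel.CF,
    "structure successful": OutcomeLabel.CR,
    # registry-era spellings of the duplicate-structure statuses; all
    # indicate the structure was solved (possibly by another center)
    "pdb duplication found": OutcomeLabel.CR,
    "pdb duplicate found": OutcomeLabel.CR,
    "targetdb duplicate target found": OutcomeLabel.CR,
}

#: current-status string -> outcome
CURRENT_STATUS_MAP: dict[str, OutcomeLabel] = {
    "crystal structure": OutcomeLabel.CR,
    "in pdb": OutcomeLabel.CR,
}


@dataclasses.dataclass(frozen=True)
class TrialStatusRecord:
    sequence_id: str
    status: str
    status_kind: str = STATUS_KIND_STOP

    def __post_init__(self) -> None:
        if not normalize_status(self.status):
            raise ValueError("status must be non-empty after normalization")
        if self.status_kind not in (STATUS_KIND_STOP, STATUS_KIND_CURRENT):
            raise ValueError(f"unknown status_kind {self.status_kind!r}")


def normalize_status(status: str) -> str:
    """Trim, collapse internal whitespace, lower-case."""
    return re.sub(r"\s+", " ", status.strip()).lower()


def map_status(record: TrialStatusRecord) -> OutcomeLabel | None:
    """Outcome for one trial record, or None when the status is unrecognized."""
    table = (
        STOP_STATUS_MAP
        if record.status_kind == STATUS_KIND_STOP
        else CURRENT_STATUS_MAP
    )
    return table.get(normalize_status(record.status))


def resolve_farthest(records: Iterable[TrialStatusRecord]) -> OutcomeLabel | None:
    """Label of the trial that reached farthest into the pipeline.

    Order-independent and idempotent; None when no record maps.
    """
    mapped = [m for m in (map_status(r) for r in records) if m is not None]
    if not mapped:
        return None
    return max(mapped, key=lambda label: label.pipeline_rank)


def read_status_table(path) -> list[TrialStatusRecord]:
    """Read a 3-column TSV: sequence_id, status_kind, status."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated columns")
            records.append(TrialStatusRecord(parts[0], parts[2], parts[1]))
    return records


def annotate_table(records: Sequence[TrialStatusRecord]) -> dict[str, OutcomeLabel]:
    """sequence_id -> resolved outcome (ids with no mapped trial are omitted)."""
    by_id: dict[str, list[TrialStatusRecord]] = {}
    for rec in records:
        by_id.setdefault(rec.sequence_id, []).append(rec)
    out: dict[str, OutcomeLabel] = {}
    for seq_id, recs in by_id.items():
        label = resolve_farthest(recs)
        if label is not None:
            out[seq_id] = label
    return out


def write_labels(labels: dict[str, OutcomeLabel], path) -> None:
    """Write a 2-column TSV: sequence_id, outcome."""
    with open(path, "w") as fh:
        fh.write("id\toutcome\n")
        for seq_id, label in labels.items():
            fh.write(f"{seq_id}\t{label.value}\n")


def read_labels(path) -> dict[str, OutcomeLabel]:
    labels: dict[str, OutcomeLabel] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["id", "outcome"]:
            raise ValueError(f"unexpected label-table header in {path}")
        for line in fh:
            if not line.strip():
                continue
            seq_id, value = line.rstrip("\n").split("\t")
            labels[seq_id] = OutcomeLabel(value)
    return labels
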