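"""The four experimental outcomes of a protein production/crystallization pipeline.

Structural-genomics trial registries record how far each target protein
progressed: material production (cloning/expression), purification,
crystallization, and finally diffraction-quality crystals that yield a solved
structure. Each protein is labelled with the terminal event of its trials.
"""

from __future__ import annotations

import enum


class OutcomeLabel(enum.Enum):
    """Terminal outcome of a production/crystallization pipeline.

    The members are ordered by pipeline stage: a protein that failed
    purification necessarily succeeded at material production, so later
    stages dominate when merging multiple trial records.
    """

    MF = "MF"  # material-production failure (cloning/sequencing/expression)
    PF = "PF"  # purification failure
    CF = "CF"  # crystallization failure (incl. poor diffraction)
    CR = "CR"  # diffraction-quality crystallization success

    @property
    def pipeline_rank(self) -> int:
        return _RANK[self]

    def __lt__(self, other: "OutcomeLabel") -> bool:
        if not isinstance(other, OutcomeLabel):
            return NotImplemented
        return self.pipeline_rank < other.pipeline_rank


_RANK = {
    OutcomeLabel.MF: 0,
    OutcomeLabel.PF: 1,
    OutcomeLabel.CF: 2,
    OutcomeLabel.CR: 3,
}

#: Outcomes in pipeline order; the canonical iteration order everywhere.
OUTCOMES = (OutcomeLabel.MF, OutcomeLabel.PF, OutcomeLabel.CF, OutcomeLabel.CR)
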