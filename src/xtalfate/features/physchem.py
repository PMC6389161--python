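"""Whole-protein physicochemical descriptors (4 features).

Isoelectric point, aliphatic index, instability index and net charge at
pH 7. Charge follows the Henderson-Hasselbalch sum over ionizable side
chains and free termini with the bundled EMBOSS pKa set; the isoelectric
point is the zero crossing of that charge curve, located by bisection. The
instability index is the Guruprasad dipeptide-weight sum as implemented in
biopython.
"""

from __future__ import annotations

import numpy as np
from Bio.SeqUtils.ProtParam import ProteinAnalysis

from .composition import aa_composition
from .tables import AA_INDEX, load_pka_set

PHYSCHEM_NAMES = (
    "PROT_isoelectric_point",
    "PROT_aliphatic_index",
    "PROT_instability_index",
    "PROT_net_charge_pH7",
)


def aliphatic_index(sequence: str) -> float:
    """Ikai's aliphatic index from mole percentages of A, V, I and L."""
    comp = aa_composition(sequence) * 100.0
    return float(
        comp[AA_INDEX["A"]]
        + 2.9 * comp[AA_INDEX["V"]]
        + 3.9 * (comp[AA_INDEX["I"]] + comp[AA_INDEX["L"]])
    )


def net_charge(sequence: str, ph: float) -> float:
    """Net charge (elementary charges) of side chains plus free termini."""
    pka = load_pka_set()
    counts = {"Nterm": 1, "Cterm": 1}
    for aa in "CDEHKRY":
        counts[aa] = sequence.count(aa)
    charge = 0.0
    for group, (pk, sign) in pka.items():
        n = counts.get(group, 0)
        if n == 0:
            continue
        if sign > 0:
            charge += n / (1.0 + 10.0 ** (ph - pk))
        else:
            charge -= n / (1.0 + 10.0 ** (pk - ph))
    return charge


def isoelectric_point(sequence: str, tol: float = 1e-3) -> float:
    """pH at which the net charge crosses zero, by bisection on [0, 14]."""
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(sequence, mid) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def instability_index(sequence: str) -> float:
    return float(ProteinAnalysis(sequence).instability_index())


def global_physchem(sequence: str) -> np.ndarray:
    """(isoelectric point, aliphatic index, instability index, charge at pH 7)."""
    return np.array(
        [
            isoelectric_point(sequence),
            aliphatic_index(sequence),
            instability_index(sequence),
            net_charge(sequence, 7.0),
        ]
    )
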