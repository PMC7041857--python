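"""Tri-peptide unfolded-state model for relative folding free energies.

The unfolded state of a designed protein is modelled per residue: for each
mutable position, type and rotamer, an input table gives the interaction
energy between the side chain and the tri-peptide formed with the adjacent
backbone groups.  A type's contribution is the energy of its best rotamer,
averaged over the mutating positions where the type is allowed; the total
unfolded energy of a sequence is the sum of its types' contributions.

Relative folding free energies (folded-state sequence free energy minus
unfolded energy, referenced to a chosen sequence) feed the stability
filter used when ranking designs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .energy_model import EnergyMatrix, load_energy_matrix

__all__ = [
    "TripeptideTable",
    "type_contribution",
    "unfolded_energy",
    "folding_free_energy",
]


class TripeptideTable:
    """Per (position, type, rotamer) tri-peptide interaction energies."""

    def __init__(self, energies: dict):
        # energies: (position, type) -> sequence of rotamer energies
        self.energies = {
            key: np.asarray(val, dtype=float) for key, val in energies.items()
        }
        for key, arr in self.energies.items():
            if arr.size == 0:
                raise ValueError(f"(position, type) {key} has no rotamer entries")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite tri-peptide energy at {key}")

    @classmethod
    def from_matrix(cls, matrix: EnergyMatrix) -> "TripeptideTable":
        """Build from a DIAG-only energy matrix (state label "unfolded")."""
        if matrix.pair:
            raise ValueError("tri-peptide table must contain DIAG records only")
        space = matrix.space
        energies = {}
        for pos in space.positions:
            for t in space.types_at(pos):
                energies[(pos, t)] = [
                    matrix.diag_energy(pos, t, r)
                    for r in range(space.rotamers_at(pos, t))
                ]
        return cls(energies)

    @classmethod
    def load(cls, path) -> "TripeptideTable":
        return cls.from_matrix(load_energy_matrix(path))

    def positions_with(self, t: str):
        return sorted(pos for (pos, typ) in self.energies if typ == t)


def type_contribution(table: TripeptideTable, t: str) -> float:
    """Best-rotamer energy of type ``t``, averaged over the mutating
    positions where the type is allowed (kcal/mol)."""
    best = [
        arr.min() for (pos, typ), arr in table.energies.items() if typ == t
    ]
    if not best:
        raise KeyError(f"type {t!r} absent from the tri-peptide table")
    return float(np.mean(best))


def unfolded_energy(table: TripeptideTable, sequence: str) -> float:
    """Total unfolded energy: sum of the per-type contributions over the
    positions of the sequence."""
    return float(sum(type_contribution(table, t) for t in sequence))


def folding_free_energy(
    g_apo: pd.Series, table: TripeptideTable, reference: str
) -> pd.Series:
    """Relative folding free energy per sequence,
    ``fold(S) = [G_apo(S) - E_unf(S)] - [G_apo(R) - E_unf(R)]``.

    ``g_apo`` holds *unbiased* apo sequence free energies (any common
    additive constant cancels).  Raises if the reference is missing.
    """
    if reference not in g_apo.index:
        raise ValueError(f"reference sequence {reference!r} missing from G_apo")
    e_unf = pd.Series(
        [unfolded_energy(table, s) for s in g_apo.index], index=g_apo.index
    )
    raw = g_apo - e_unf
    out = (raw - raw.loc[reference]).astype(float)
    out.name = "fold"
    return out
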