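"""Reference data for the E. coli methionyl-tRNA synthetase (MetRS)
active-site redesign problems.

Two published design spaces over three active-site positions each:

- azidonorleucine (AnL) binding: positions 13, 260, 301, fourteen allowed
  types per position (Tyr replaces Asp at 260), 14^3 = 2744 sequences;
- methionyl-adenylate (MetAMP) binding: positions 13, 256, 297, all types
  except Gly and Pro, 18^3 = 5832 sequences.

Also included: the published per-variant folding and binding free-energy
columns (kcal/mol, relative to the reference sequence of each study) used
as worked examples for the stability filter and ranking — the AnL study
references the X-ray sequence SLL and filters at 7 kcal/mol; the MetAMP
study references wild type LAI and filters at 5 kcal/mol.  These numbers
are inputs (published table columns), not outputs of this package.
"""

from __future__ import annotations

import pandas as pd

from .energy_model import SequenceSpace

__all__ = [
    "anl_design_space",
    "metamp_design_space",
    "anl_variant_table",
    "metamp_variant_table",
    "ANL_REFERENCE",
    "METAMP_REFERENCE",
    "ANL_FOLD_THRESHOLD",
    "METAMP_FOLD_THRESHOLD",
]

ANL_REFERENCE = "SLL"  # X-ray sequence at positions 13, 260, 301
METAMP_REFERENCE = "LAI"  # wild type at positions 13, 256, 297
ANL_FOLD_THRESHOLD = 7.0  # kcal/mol
METAMP_FOLD_THRESHOLD = 5.0  # kcal/mol

_ANL_TYPES_13_301 = "ACDEHIKLMNQSTV"
_ANL_TYPES_260 = "ACEHIKLMNQSTVY"  # Tyr replaces Asp
_METAMP_TYPES = "ACDEFHIKLMNQRSTVWY"  # all but Gly, Pro


def anl_design_space(rotamers: int = 1) -> SequenceSpace:
    """The AnL-binding design space (2744 sequences)."""
    return SequenceSpace(
        positions=[13, 260, 301],
        allowed_types=[_ANL_TYPES_13_301, _ANL_TYPES_260, _ANL_TYPES_13_301],
        rotamer_counts=rotamers,
    )


def metamp_design_space(rotamers: int = 1) -> SequenceSpace:
    """The MetAMP-binding design space (5832 sequences)."""
    return SequenceSpace(
        positions=[13, 256, 297],
        allowed_types=[_METAMP_TYPES] * 3,
        rotamer_counts=rotamers,
    )


# Published AnL variants (positions 13/260/301): folding, binding and
# specificity free energies (kcal/mol) relative to SLL.
_ANL_ROWS = [
    ("NLL", 6.7, 0.3, 5.7),
    ("SLL", 0.0, 0.0, 0.0),
    ("SML", 4.6, -0.5, 8.3),
    ("AVL", 6.7, -0.1, 11.0),
    ("AQL", 4.2, 0.0, 3.3),
    ("CLL", -0.6, 0.1, 1.0),
    ("CVL", 6.9, -0.4, 10.9),
    ("ACL", 5.0, 0.2, 11.0),
    ("SCM", -0.9, 0.4, 18.8),
    ("SLV", -2.3, 1.4, 7.4),
    ("SNL", 7.6, 0.0, 10.2),
    ("SSL", 7.2, -0.1, 10.3),
    ("STL", 7.2, 0.6, 10.2),
]

# Published MetAMP variants (positions 13/256/297): folding and computed
# binding free energies (kcal/mol) relative to LAI.
_METAMP_ROWS = [
    ("CDV", 4.5, -1.36),
    ("MAV", 1.3, -0.23),
    ("MAI", 2.5, -0.20),
    ("LAV", -1.3, -0.16),
    ("MAC", 2.3, -0.09),
    ("LAI", 0.0, 0.00),
    ("MAA", 2.0, 0.02),
    ("MSV", 3.1, 0.11),
    ("MSI", 4.4, 0.15),
    ("LSI", 1.6, 0.20),
    ("LAC", -0.3, 0.25),
    ("MAT", 4.6, 0.28),
    ("LSV", 0.4, 0.29),
    ("LAA", -0.6, 0.31),
    ("CAV", -8.8, 0.34),
    ("CAI", -7.4, 0.37),
    ("MSC", 4.1, 0.45),
    ("MCV", 1.0, 0.46),
    ("MCI", 2.3, 0.48),
    ("MSA", 3.8, 0.56),
    ("LAT", 1.8, 0.59),
    ("CAC", -7.9, 0.69),
    ("SAI", -3.5, 0.72),
    ("SAC", -4.0, 1.11),
    ("LAS", 1.3, 1.34),
    ("SSI", -1.9, 1.35),
    ("SSC", -2.2, 1.45),
    ("MST", 6.2, 0.98),
    ("MSS", 5.8, 1.64),
]


def anl_variant_table() -> pd.DataFrame:
    """Published AnL variant energies, indexed by sequence; columns
    ``fold``, ``ddG_bind``, ``ddG_spec``."""
    df = pd.DataFrame(
        _ANL_ROWS, columns=["sequence", "fold", "ddG_bind", "ddG_spec"]
    )
    return df.set_index("sequence")


def metamp_variant_table() -> pd.DataFrame:
    """Published MetAMP variant energies, indexed by sequence; columns
    ``fold``, ``ddG_bind``."""
    df = pd.DataFrame(_METAMP_ROWS, columns=["sequence", "fold", "ddG_bind"])
    return df.set_index("sequence")
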