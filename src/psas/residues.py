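"""Canonical amino-acid identifiers.

The canonical form used throughout the package is the three-letter code
(``"Trp"``). One-letter codes and arbitrary letter case are accepted on
input. The canonical residue order is the row order of the packaged index
table (aromatic solutes first, then the remaining residues grouped roughly
by side-chain chemistry); this order is used for deterministic tie-breaking
and for matrix row/column layout.
"""

from __future__ import annotations

__all__ = [
    "CANONICAL_RESIDUES",
    "AROMATIC_RESIDUES",
    "ONE_TO_THREE",
    "THREE_TO_ONE",
    "MOLAR_MASS",
    "ResidueError",
    "canonical_residue",
    "canonical_sort_key",
]

#: Canonical residue order (index-table row order).
CANONICAL_RESIDUES: tuple[str, ...] = (
    "Tyr", "Trp", "Phe", "Arg", "Lys", "His", "Pro", "Gly", "Ala", "Ser",
    "Cys", "Met", "Val", "Leu", "Ile", "Thr", "Gln", "Asn", "Glu", "Asp",
)

#: The three aromatic amino acids used as solutes in the solubility assays.
AROMATIC_RESIDUES: tuple[str, ...] = ("Tyr", "Trp", "Phe")

ONE_TO_THREE: dict[str, str] = {
    "Y": "Tyr", "W": "Trp", "F": "Phe", "R": "Arg", "K": "Lys", "H": "His",
    "P": "Pro", "G": "Gly", "A": "Ala", "S": "Ser", "C": "Cys", "M": "Met",
    "V": "Val", "L": "Leu", "I": "Ile", "T": "Thr", "Q": "Gln", "N": "Asn",
    "E": "Glu", "D": "Asp",
}

THREE_TO_ONE: dict[str, str] = {three: one for one, three in ONE_TO_THREE.items()}

#: Molar masses of the free amino acids, g/mol (monoisotopic-independent,
#: standard atomic weights). Used to convert aqueous solubilities expressed
#: in g per 100 mL into molar concentrations.
MOLAR_MASS: dict[str, float] = {
    "Gly": 75.07, "Ala": 89.09, "Ser": 105.09, "Pro": 115.13, "Val": 117.15,
    "Thr": 119.12, "Cys": 121.16, "Leu": 131.17, "Ile": 131.17, "Asn": 132.12,
    "Asp": 133.10, "Gln": 146.15, "Lys": 146.19, "Glu": 147.13, "Met": 149.21,
    "His": 155.15, "Phe": 165.19, "Arg": 174.20, "Tyr": 181.19, "Trp": 204.23,
}

_NORMALIZED: dict[str, str] = {}
for _three in CANONICAL_RESIDUES:
    _NORMALIZED[_three.lower()] = _three
    _NORMALIZED[THREE_TO_ONE[_three].lower()] = _three


class ResidueError(ValueError):
    """Raised for identifiers outside the 20 canonical amino acids."""


def canonical_residue(code: str) -> str:
    """Normalize a residue identifier to its canonical three-letter form.

    Accepts one-letter and three-letter codes in any case.

    Raises
    ------
    ResidueError
        If ``code`` does not name one of the 20 canonical residues.
    """
    if not isinstance(code, str):
        raise ResidueError(f"residue identifier must be a string, got {type(code).__name__}")
    try:
        return _NORMALIZED[code.strip().lower()]
    except KeyError:
        raise ResidueError(
            f"unknown residue {code!r}; expected a one- or three-letter code "
            f"for one of the 20 canonical amino acids"
        ) from None


def canonical_sort_key(residue: str) -> int:
    """Position of a residue in the canonical (index-table) row order."""
    return CANONICAL_RESIDUES.index(canonical_residue(residue))
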