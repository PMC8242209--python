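"""Named amino-acid scales with lookup, ranking and tabular I/O.

The packaged default index set collects eight classical per-residue scales
from the protein-solubility literature: aqueous solubility of the free
amino acid, Fauchere-Pliska side-chain hydrophobicity, the Miller
interior/exterior propensity, Kyte-Doolittle hydropathy, Chou-Fasman
alpha-helix / beta-sheet / coil conformational propensities, and
aromaphilicity (binding affinity of a residue for aromatic rings). Fitted
solubility-slope (PSAS) columns can be added as additional scales, which
makes ranking and correlation machinery uniform across classical and
fitted indices.

CSV schema: header ``residue,<scale1>,<scale2>,...``; one row per residue,
three-letter codes, ``.`` decimal separator. The Unicode minus sign is
normalized to ASCII ``-`` on read.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .residues import (
    CANONICAL_RESIDUES,
    ResidueError,
    canonical_residue,
    canonical_sort_key,
)

__all__ = [
    "PACKAGED_DEFAULT",
    "DEFAULT_SCALES",
    "Scale",
    "IndexSet",
    "IndexSchemaError",
    "load_index_set",
    "get_value",
    "rank_residues",
]

#: Sentinel accepted by :func:`load_index_set` for the packaged default set.
PACKAGED_DEFAULT = "default"

#: Names of the eight packaged scales, in column order.
DEFAULT_SCALES: tuple[str, ...] = (
    "solubility_in_water",
    "side_chain_hydrophobicity",
    "in_out_propensity",
    "hydropathy",
    "alpha_helix",
    "beta_sheet",
    "coil",
    "aromaphilicity",
)

_DEFAULT_METADATA: dict[str, tuple[str, str]] = {
    # scale -> (source citation, direction note)
    "solubility_in_water": (
        "Dalton & McMeekin (1935), aqueous solubility of the free amino acid",
        "larger = more soluble in water; stored as printed (units not stated "
        "in the source table, nominally g per 100 mL)",
    ),
    "side_chain_hydrophobicity": (
        "Fauchere & Pliska (1983), octanol/water transfer free energy minus Gly",
        "larger = more hydrophobic side chain",
    ),
    "in_out_propensity": (
        "Miller et al. (1987), interior/exterior propensity from crystal structures",
        "larger = more often buried in the protein interior",
    ),
    "hydropathy": (
        "Kyte & Doolittle (1982), hydropathy index",
        "larger = more hydrophobic",
    ),
    "alpha_helix": (
        "Chou & Fasman (1974), alpha-helix conformational propensity",
        "larger = stronger helix former",
    ),
    "beta_sheet": (
        "Chou & Fasman (1974), beta-sheet conformational propensity",
        "larger = stronger sheet former",
    ),
    "coil": (
        "Chou & Fasman (1974), coil conformational propensity",
        "larger = stronger coil former",
    ),
    "aromaphilicity": (
        "Hirano & Kameda (2021), binding affinity to aromatic rings",
        "larger = stronger affinity for aromatic rings",
    ),
}


class IndexSchemaError(ValueError):
    """Raised when an index table violates the CSV schema."""


@dataclass(frozen=True)
class Scale:
    """One named amino-acid scale: a complete residue -> value mapping."""

    name: str
    values: dict[str, float]
    citation: str = ""
    direction: str = ""

    def __post_init__(self) -> None:
        missing = [r for r in CANONICAL_RESIDUES if r not in self.values]
        if missing:
            raise IndexSchemaError(
                f"scale {self.name!r} is missing residues: {', '.join(missing)}"
            )
        extra = [r for r in self.values if r not in CANONICAL_RESIDUES]
        if extra:
            raise IndexSchemaError(
                f"scale {self.name!r} has non-canonical residues: {', '.join(extra)}"
            )

    def __getitem__(self, residue: str) -> float:
        return self.values[canonical_residue(residue)]


@dataclass
class IndexSet:
    """A named collection of amino-acid scales."""

    scales: dict[str, Scale] = field(default_factory=dict)

    @property
    def names(self) -> list[str]:
        return list(self.scales)

    def __contains__(self, name: str) -> bool:
        return name in self.scales

    def __getitem__(self, name: str) -> Scale:
        try:
            return self.scales[name]
        except KeyError:
            raise KeyError(
                f"unknown index {name!r}; available: {', '.join(self.scales)}"
            ) from None

    def add(self, scale: Scale) -> None:
        self.scales[scale.name] = scale

    def to_frame(self) -> pd.DataFrame:
        """Scales as a residue x scale DataFrame in canonical row order."""
        return pd.DataFrame(
            {name: [s.values[r] for r in CANONICAL_RESIDUES] for name, s in self.scales.items()},
            index=pd.Index(CANONICAL_RESIDUES, name="residue"),
        )

    def to_csv(self, path: str | Path) -> None:
        """Write the set in the index CSV schema (round-trips with load)."""
        self.to_frame().to_csv(path)


def _parse_index_frame(df: pd.DataFrame, origin: str) -> IndexSet:
    if "residue" not in df.columns:
        raise IndexSchemaError(f"{origin}: first column must be 'residue'")
    scale_names = [c for c in df.columns if c != "residue"]
    if not scale_names:
        raise IndexSchemaError(f"{origin}: no scale columns found")

    residues = []
    for raw in df["residue"]:
        try:
            residues.append(canonical_residue(str(raw)))
        except ResidueError as exc:
            raise IndexSchemaError(f"{origin}: {exc}") from None
    dupes = {r for r in residues if residues.count(r) > 1}
    if dupes:
        raise IndexSchemaError(f"{origin}: duplicate residue rows: {', '.join(sorted(dupes))}")
    missing = [r for r in CANONICAL_RESIDUES if r not in residues]
    if missing:
        raise IndexSchemaError(f"{origin}: missing residue rows: {', '.join(missing)}")

    out = IndexSet()
    for name in scale_names:
        values: dict[str, float] = {}
        for residue, cell in zip(residues, df[name]):
            text = str(cell).replace("−", "-").strip()
            try:
                values[residue] = float(text)
            except ValueError:
                raise IndexSchemaError(
                    f"{origin}: non-numeric cell {cell!r} at row {residue}, column {name}"
                ) from None
        citation, direction = _DEFAULT_METADATA.get(name, ("", ""))
        out.add(Scale(name=name, values=values, citation=citation, direction=direction))
    return out


def load_index_set(source: str | Path = PACKAGED_DEFAULT) -> IndexSet:
    """Load an index set from a CSV file or the packaged default.

    Parameters
    ----------
    source
        Path to a CSV in the index schema, or the sentinel ``"default"``
        for the packaged eight-scale table.

    Raises
    ------
    IndexSchemaError
        On a missing/duplicate residue row or a non-numeric cell.
    """
    if isinstance(source, str) and source == PACKAGED_DEFAULT:
        text = resources.files("psas.data").joinpath("classical_indices.csv").read_text("utf-8")
        df = pd.read_csv(io.StringIO(text), dtype=str)
        return _parse_index_frame(df, "packaged default")
    path = Path(source)
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise IndexSchemaError(f"{path}: empty index file") from None
    if df.empty:
        raise IndexSchemaError(f"{path}: index file has no residue rows")
    return _parse_index_frame(df, str(path))


def get_value(index_set: IndexSet, index_name: str, residue: str) -> float:
    """Look up one cell of an index set.

    Raises ``KeyError`` (listing available scales) for an unknown scale and
    :class:`~psas.residues.ResidueError` for an unknown residue.
    """
    return index_set[index_name][canonical_residue(residue)]


def rank_residues(
    index_set: IndexSet,
    index_name: str,
    descending: bool = False,
) -> list[str]:
    """Residues ordered by an index value.

    Ties are broken by canonical (packaged-table) row order, so the output
    is deterministic for any input scale.
    """
    scale = index_set[index_name]
    return sorted(
        CANONICAL_RESIDUES,
        key=lambda r: (-scale.values[r] if descending else scale.values[r], canonical_sort_key(r)),
    )
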