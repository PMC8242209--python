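"""Comparison of fitted solubility slopes with classical amino-acid scales.

Two complementary views mirror how a fitted interaction matrix is read:

* **by row** — one solute's slope profile across the 20 solvents is
  rank-correlated (Spearman by default, Kendall tau-b as a tie-robust
  alternative) against each classical scale, asking which physical
  property of the *solvent* residues the slopes track;
* **by column** — within each solvent, the three aromatic solutes are
  ordered by slope and the ordering string is matched against the
  orderings the classical scales induce on {Tyr, Trp, Phe}. Solubilizing
  solvents are expected to follow the aromaphilicity order (Trp>Tyr>Phe),
  insolubilizing ones the water-solubility or side-chain-hydrophobicity
  orders.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .index_db import IndexSet
from .psas_fit import InteractionClass, PSASMatrix
from .residues import canonical_residue

__all__ = [
    "UndefinedCorrelationError",
    "ComparisonReport",
    "rank_correlation",
    "row_compare",
    "column_order",
    "index_order",
    "order_string",
    "consistency_report",
    "REFERENCE_INDICES",
]

#: Classical scales a fitted matrix is matched against in the report.
REFERENCE_INDICES = ("solubility_in_water", "side_chain_hydrophobicity", "aromaphilicity")

CorrelationMethod = Literal["spearman", "kendall"]


class UndefinedCorrelationError(ValueError):
    """A rank correlation is undefined (constant input vector)."""


def rank_correlation(
    a: Sequence[float],
    b: Sequence[float],
    method: CorrelationMethod = "spearman",
) -> float:
    """Rank correlation of two paired value vectors.

    Spearman is the Pearson correlation of mid-ranks; Kendall is tau-b
    (tie-corrected). Vectors must be paired, of equal length >= 3.

    Raises
    ------
    UndefinedCorrelationError
        If either vector is constant (the coefficient is undefined, and is
        reported as an error rather than silently as 0 or NaN).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("vectors must be one-dimensional and of equal length")
    if len(a) < 3:
        raise ValueError("rank correlation needs at least 3 paired values")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedCorrelationError("rank correlation undefined for a constant vector")
    if method == "spearman":
        return float(stats.spearmanr(a, b).statistic)
    if method == "kendall":
        return float(stats.kendalltau(a, b, variant="b").statistic)
    raise ValueError(f"unknown method {method!r}; use 'spearman' or 'kendall'")


def row_compare(
    matrix: PSASMatrix,
    solute: str,
    index_set: IndexSet,
    indices: Sequence[str] | None = None,
    method: CorrelationMethod = "spearman",
) -> dict[str, float]:
    """Rank-correlate one solute's slope profile against reference scales.

    The profile and each scale are paired by solvent residue over all
    solvents in the matrix. Returns one coefficient per scale.
    """
    profile = matrix.row(solute)  # raises KeyError for an unknown solute
    names = list(indices) if indices is not None else list(index_set.names)
    out: dict[str, float] = {}
    for name in names:
        scale = index_set[name]
        ref = [scale.values[sv] for sv in profile.index]
        out[name] = rank_correlation(profile.to_numpy(), ref, method=method)
    return out


def order_string(values: Mapping[str, float], residues: Sequence[str] | None = None) -> str:
    """Render residues ordered by descending value, ties joined with ``=``.

    Tied residues are listed alphabetically within their group, so the
    string is deterministic.
    """
    residues = list(values) if residues is None else [canonical_residue(r) for r in residues]
    ordered = sorted(residues, key=lambda r: (-values[r], r))
    parts: list[str] = []
    for i, r in enumerate(ordered):
        if i == 0:
            parts.append(r)
        elif values[r] == values[ordered[i - 1]]:
            parts.append("=" + r)
        else:
            parts.append(">" + r)
    return "".join(parts)


def column_order(matrix: PSASMatrix, solvent: str) -> str:
    """Ordering string of the solutes by descending slope in one solvent."""
    col = matrix.column(solvent)  # raises KeyError for an unknown solvent
    return order_string(col.to_dict(), matrix.solutes)


def index_order(index_set: IndexSet, index_name: str, residues: Sequence[str]) -> str:
    """Ordering string a classical scale induces on a residue subset."""
    scale = index_set[index_name]
    residues = [canonical_residue(r) for r in residues]
    return order_string({r: scale.values[r] for r in residues}, residues)


@dataclass
class ComparisonReport:
    """Comparison of a fitted slope matrix against classical scales."""

    by_row: pd.DataFrame        # solute x reference-index rank correlations
    by_column: pd.DataFrame     # per solvent: class, ordering, per-index match flags
    solvent_groups: dict[str, list[str]]  # class label -> solvents
    method: CorrelationMethod

    def to_text(self) -> str:
        lines = ["By-row rank correlations (%s):" % self.method, self.by_row.to_string(), ""]
        lines += ["By-column solute orderings:", self.by_column.to_string(), ""]
        for label in ("soluble", "insoluble", "neutral"):
            group = self.solvent_groups.get(label, [])
            lines.append(f"{label} solvents: {', '.join(group) if group else '(none)'}")
        return "\n".join(lines)


def consistency_report(
    matrix: PSASMatrix,
    index_set: IndexSet,
    classes: Mapping[str, InteractionClass],
    indices: Sequence[str] = REFERENCE_INDICES,
    method: CorrelationMethod = "spearman",
) -> ComparisonReport:
    """Full by-row / by-column comparison report.

    ``classes`` is the per-solvent interaction classification (e.g. from
    :func:`psas.psas_fit.classify_matrix`). For each solvent the report
    records its solute ordering string and whether that string matches the
    ordering each reference scale induces on the solute set.
    """
    by_row = pd.DataFrame(
        {sol: row_compare(matrix, sol, index_set, indices, method) for sol in matrix.solutes}
    ).T
    by_row.index.name = "solute"

    ref_orders = {name: index_order(index_set, name, matrix.solutes) for name in indices}
    rows = []
    for sv in matrix.solvents:
        ordering = column_order(matrix, sv)
        row = {
            "solvent": sv,
            "class": classes[sv].label,
            "ordering": ordering,
        }
        for name in indices:
            row[f"matches_{name}"] = ordering == ref_orders[name]
        rows.append(row)
    by_column = pd.DataFrame(rows).set_index("solvent")

    groups: dict[str, list[str]] = {"soluble": [], "insoluble": [], "neutral": []}
    for sv in matrix.solvents:
        groups[classes[sv].label].append(sv)

    return ComparisonReport(by_row=by_row, by_column=by_column, solvent_groups=groups, method=method)
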