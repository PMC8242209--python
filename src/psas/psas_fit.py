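"""PSAS estimation: calibration, normalization, slope fitting, matrix
assembly and interaction classification.

The solubility slope (PSAS) of a (solute, solvent) pair is the slope of
the solubility ratio r(c) = s(c)/s0 against solvent concentration c, with
the plain-buffer solubility s0 normalized to 1:

    PSAS = dr / dc      [per M]

A positive slope means the solvent amino acid solubilizes the aromatic
solute (droplet-like, "soluble" interaction); a negative slope means it
insolubilizes it (aggregate-like, "insoluble" interaction); slopes within
a small threshold of zero are classified neutral.

Because the ratio is 1 in plain buffer by construction, the default fit
constrains the intercept to 1 and estimates the slope of (r - 1) on c
through the origin, with the closed form sum(c*(r-1)) / sum(c^2). An
ordinary free-intercept least-squares fit is available as a robustness
check. All concentration points enter one fit; no segmentation by
concentration range is performed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .assay_sim import AssayRecord, StandardCurve
from .residues import AROMATIC_RESIDUES, CANONICAL_RESIDUES, canonical_residue

__all__ = [
    "SolubilityCurve",
    "PSASEntry",
    "PSASMatrix",
    "InteractionClass",
    "CalibrationError",
    "BaselineError",
    "FitError",
    "MatrixError",
    "calibrate",
    "to_ratio",
    "fit_psas",
    "fit_matrix",
    "build_matrix",
    "classify",
    "classify_matrix",
    "DEFAULT_TAU",
]

FitMode = Literal["fixed", "free"]

#: Default neutral band half-width, per M.
DEFAULT_TAU = 0.05


class CalibrationError(ValueError):
    """Absorbance cannot be inverted to a non-negative solubility."""


class BaselineError(ValueError):
    """The water (0 M) baseline is missing or non-positive."""


class FitError(ValueError):
    """The curve cannot support a slope fit."""


class MatrixError(ValueError):
    """Entries do not form a complete, duplicate-free grid."""


def calibrate(absorbance: float, curve: StandardCurve, dilution: float = 1.0) -> float:
    """Invert a standard curve: solubility = dilution*(A - intercept)/slope.

    Raises
    ------
    CalibrationError
        If the absorbance lies below the curve intercept (a negative
        concentration) or the dilution is below 1.
    """
    if dilution < 1:
        raise CalibrationError(f"dilution factor must be >= 1, got {dilution}")
    if absorbance < curve.intercept:
        raise CalibrationError(
            f"absorbance {absorbance:g} below curve intercept {curve.intercept:g} "
            f"for {curve.solute}: negative concentration"
        )
    return dilution * (absorbance - curve.intercept) / curve.slope


@dataclass
class SolubilityCurve:
    """Normalized ratio-vs-concentration series for one (solute, solvent) pair."""

    solute: str
    solvent: str
    s0: float                         # water-baseline solubility
    conc: np.ndarray                  # sorted, M
    ratio: np.ndarray                 # s/s0, dimensionless; 1 at c=0
    n_replicates: np.ndarray          # replicates folded into each point
    fittable: bool = True

    def __post_init__(self) -> None:
        order = np.argsort(self.conc)
        self.conc = np.asarray(self.conc, dtype=float)[order]
        self.ratio = np.asarray(self.ratio, dtype=float)[order]
        self.n_replicates = np.asarray(self.n_replicates, dtype=int)[order]
        if (self.conc < 0).any():
            raise ValueError("negative solvent concentration")
        if len(np.unique(self.conc)) < 2:
            self.fittable = False


def to_ratio(records: Iterable[AssayRecord], s0: float | None = None) -> SolubilityCurve:
    """Fold replicate records of one pair into a normalized solubility curve.

    Replicates are averaged per concentration (unweighted); the baseline
    solubility s0 is the mean of the 0 M records unless given explicitly,
    and every mean is divided by it, so the 0 M point has ratio exactly 1.

    Raises
    ------
    BaselineError
        If there is no 0 M record and no explicit s0, or if s0 <= 0.
    ValueError
        If the records span more than one (solute, solvent) pair.
    """
    records = list(records)
    if not records:
        raise ValueError("no assay records supplied")
    pairs = {(r.solute, r.solvent) for r in records}
    if len(pairs) > 1:
        raise ValueError(f"records span multiple (solute, solvent) pairs: {sorted(pairs)}")
    solute, solvent = pairs.pop()

    df = pd.DataFrame({"conc": [r.conc for r in records], "s": [r.solubility for r in records]})
    grouped = df.groupby("conc", sort=True)["s"].agg(["mean", "size"])

    if s0 is None:
        if 0.0 not in grouped.index:
            raise BaselineError(
                f"no 0 M baseline records for {solute} in {solvent}; "
                "supply the water solubility s0 explicitly"
            )
        s0 = float(grouped.loc[0.0, "mean"])
    if s0 <= 0:
        raise BaselineError(f"baseline solubility must be positive, got {s0:g}")

    return SolubilityCurve(
        solute=solute,
        solvent=solvent,
        s0=float(s0),
        conc=grouped.index.to_numpy(dtype=float),
        ratio=grouped["mean"].to_numpy(dtype=float) / s0,
        n_replicates=grouped["size"].to_numpy(dtype=int),
    )


@dataclass(frozen=True)
class PSASEntry:
    """Fitted solubility slope for one (solute, solvent) pair."""

    solute: str
    solvent: str
    psas: float            # slope, per M
    stderr: float          # standard error of the slope
    r2: float              # goodness of fit (<= 1)
    n_points: int
    fit_mode: FitMode


def fit_psas(curve: SolubilityCurve, mode: FitMode = "fixed") -> PSASEntry:
    """Fit the solubility slope of one normalized curve.

    ``fixed`` (default) constrains the line through (0, 1): the slope of
    (ratio - 1) on c through the origin, closed form
    sum(c_i*(r_i - 1)) / sum(c_i^2), with the standard error from the
    through-origin residual variance on n-1 degrees of freedom and an
    uncentered R^2 (1 - RSS / sum((r-1)^2)). ``free`` is ordinary least
    squares of ratio on c.

    Raises
    ------
    FitError
        If fewer than two distinct concentrations are available.
    """
    if not curve.fittable or len(np.unique(curve.conc)) < 2:
        raise FitError(
            f"cannot fit {curve.solute} in {curve.solvent}: need at least two "
            "distinct solvent concentrations"
        )
    c = curve.conc
    y = curve.ratio - 1.0
    n = len(c)

    if mode == "fixed":
        scc = float(np.dot(c, c))
        slope = float(np.dot(c, y)) / scc
        resid = y - slope * c
        rss = float(np.dot(resid, resid))
        tss = float(np.dot(y, y))
        dof = n - 1
        stderr = float(np.sqrt(rss / dof / scc)) if dof > 0 else 0.0
        r2 = 1.0 if tss == 0.0 else 1.0 - rss / tss
    elif mode == "free":
        res = stats.linregress(c, curve.ratio)
        slope = float(res.slope)
        stderr = float(res.stderr) if np.isfinite(res.stderr) else 0.0
        r2 = float(res.rvalue) ** 2
    else:
        raise ValueError(f"unknown fit mode {mode!r}; use 'fixed' or 'free'")

    return PSASEntry(
        solute=curve.solute,
        solvent=curve.solvent,
        psas=slope,
        stderr=stderr,
        r2=r2,
        n_points=n,
        fit_mode=mode,
    )


@dataclass
class PSASMatrix:
    """Complete solutes x solvents grid of fitted slopes."""

    solutes: tuple[str, ...]
    solvents: tuple[str, ...]
    entries: dict[tuple[str, str], PSASEntry]

    def entry(self, solute: str, solvent: str) -> PSASEntry:
        key = (canonical_residue(solute), canonical_residue(solvent))
        if key not in self.entries:
            raise KeyError(f"no entry for solute {key[0]} in solvent {key[1]}")
        return self.entries[key]

    def value(self, solute: str, solvent: str) -> float:
        return self.entry(solute, solvent).psas

    def row(self, solute: str) -> pd.Series:
        """One solute's slope profile across all solvents."""
        solute = canonical_residue(solute)
        if solute not in self.solutes:
            raise KeyError(f"solute {solute} not in matrix (solutes: {self.solutes})")
        return pd.Series(
            [self.entries[(solute, sv)].psas for sv in self.solvents],
            index=pd.Index(self.solvents, name="solvent"),
            name=solute,
        )

    def column(self, solvent: str) -> pd.Series:
        """All solutes' slopes in one solvent."""
        solvent = canonical_residue(solvent)
        if solvent not in self.solvents:
            raise KeyError(f"solvent {solvent} not in matrix")
        return pd.Series(
            [self.entries[(sol, solvent)].psas for sol in self.solutes],
            index=pd.Index(self.solutes, name="solute"),
            name=solvent,
        )

    def to_frame(self) -> pd.DataFrame:
        """Solvent rows (canonical order) x solute columns."""
        return pd.DataFrame(
            {sol: [self.entries[(sol, sv)].psas for sv in self.solvents] for sol in self.solutes},
            index=pd.Index(self.solvents, name="solvent"),
        )

    def diagnostics(self) -> pd.DataFrame:
        """Per-pair fit diagnostics (slope, stderr, r2, n_points)."""
        rows = []
        for sv in self.solvents:
            for sol in self.solutes:
                e = self.entries[(sol, sv)]
                rows.append(
                    {
                        "solute": sol,
                        "solvent": sv,
                        "psas": e.psas,
                        "stderr": e.stderr,
                        "r2": e.r2,
                        "n_points": e.n_points,
                        "fit_mode": e.fit_mode,
                    }
                )
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def build_matrix(
    entries: Iterable[PSASEntry],
    solutes: Sequence[str] = AROMATIC_RESIDUES,
    solvents: Sequence[str] = CANONICAL_RESIDUES,
) -> PSASMatrix:
    """Assemble fitted entries into a complete matrix.

    Row/column order is deterministic: solvents in canonical table order,
    solutes Tyr, Trp, Phe by default.

    Raises
    ------
    MatrixError
        On a duplicate (solute, solvent) pair or an incomplete grid.
    """
    solutes = tuple(canonical_residue(s) for s in solutes)
    solvents = tuple(canonical_residue(s) for s in solvents)
    table: dict[tuple[str, str], PSASEntry] = {}
    for e in entries:
        key = (e.solute, e.solvent)
        if key in table:
            raise MatrixError(f"duplicate entry for solute {key[0]} in solvent {key[1]}")
        table[key] = e
    missing = [(sol, sv) for sv in solvents for sol in solutes if (sol, sv) not in table]
    if missing:
        gaps = ", ".join(f"{sol}/{sv}" for sol, sv in missing[:8])
        more = "" if len(missing) <= 8 else f" (+{len(missing) - 8} more)"
        raise MatrixError(f"missing entries for pairs: {gaps}{more}")
    extra = [k for k in table if k[0] not in solutes or k[1] not in solvents]
    if extra:
        raise MatrixError(f"entries outside the requested grid: {extra[:8]}")
    return PSASMatrix(solutes=solutes, solvents=solvents, entries=table)


def fit_matrix(
    records: Iterable[AssayRecord],
    mode: FitMode = "fixed",
    solutes: Sequence[str] = AROMATIC_RESIDUES,
    solvents: Sequence[str] = CANONICAL_RESIDUES,
) -> PSASMatrix:
    """Full pipeline from assay records to a fitted matrix: group records
    by pair, normalize each to its water baseline, fit slopes, assemble."""
    groups: dict[tuple[str, str], list[AssayRecord]] = {}
    for r in records:
        groups.setdefault((r.solute, r.solvent), []).append(r)
    entries = [fit_psas(to_ratio(recs), mode=mode) for recs in groups.values()]
    return build_matrix(entries, solutes=solutes, solvents=solvents)


@dataclass(frozen=True)
class InteractionClass:
    """Soluble / insoluble / neutral call for one fitted slope."""

    label: Literal["soluble", "insoluble", "neutral"]
    tau: float
    psas: float

    def __str__(self) -> str:
        return self.label


def classify(entry: PSASEntry | float, tau: float = DEFAULT_TAU) -> InteractionClass:
    """Classify a slope: soluble if psas > tau, insoluble if psas < -tau,
    neutral otherwise. ``tau`` (per M) must be non-negative."""
    if tau < 0:
        raise ValueError("tau must be non-negative")
    psas = entry.psas if isinstance(entry, PSASEntry) else float(entry)
    if psas > tau:
        label = "soluble"
    elif psas < -tau:
        label = "insoluble"
    else:
        label = "neutral"
    return InteractionClass(label=label, tau=tau, psas=psas)


def classify_matrix(matrix: PSASMatrix, tau: float = DEFAULT_TAU) -> dict[str, InteractionClass]:
    """Per-solvent class from the mean slope across solutes.

    A solvent's interaction class summarizes its column; the mean over the
    three aromatic solutes is used as the column summary.
    """
    return {
        sv: classify(float(matrix.column(sv).mean()), tau=tau) for sv in matrix.solvents
    }
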