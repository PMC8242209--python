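"""Synthetic solubility-assay generator.

Emulates saturation-solubility measurements of the three aromatic amino
acids (Tyr, Trp, Phe) dissolved in buffers containing one of the 20 amino
acids as a cosolvent ("amino acid solvent"), on a per-solvent concentration
grid. Each (solute, solvent) pair carries a ground-truth solubility slope
(the true PSAS, in ratio units per molar): the measured saturation
solubility follows

    s(c) = s0 * (1 + psas * c + nonlinearity * c^2) + eps,
    eps ~ Normal(0, (noise_sd * s0)^2), truncated at 0,

where ``s0`` is the solute's solubility in plain buffer and ``c`` the
solvent concentration in M. An optional observation layer converts
solubilities to UV absorbances through per-solute standard curves after a
feasible dilution, mirroring spectrophotometric quantification at
260-280 nm.

The ``paper_like`` preset encodes the qualitative interaction structure
reported for this system: aromatic, Arg, His and Pro solvents solubilize
the aromatic solutes (positive slopes, aromatic solvents strongest);
anionic (Glu, Asp), amide (Gln, Asn) and hydrophobic solvents insolubilize
them (Glu/Asp most negative); Gly, Ser, Thr and Lys are inert. True slope
magnitudes are set by a fixed relative solubility change at each solvent's
maximum usable concentration, so sparingly soluble solvents (small cmax)
carry the largest per-molar slopes — exactly the pattern that makes the
aromatic solvents the strongest solubilizers per mole.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .index_db import load_index_set
from .residues import (
    AROMATIC_RESIDUES,
    CANONICAL_RESIDUES,
    MOLAR_MASS,
    canonical_residue,
)

__all__ = [
    "Scenario",
    "Design",
    "StandardCurve",
    "AssayRecord",
    "PRESETS",
    "default_cmax",
    "default_s0",
    "default_standard_curves",
    "make_scenario",
    "simulate_assay",
    "observe_absorbance",
    "records_to_frame",
    "frame_to_records",
    "write_assay_csv",
    "read_assay_csv",
    "DilutionError",
]

#: Grams-per-100-mL -> mol/L conversion: c[M] = value * G100ML_TO_MOLAR / MW.
G100ML_TO_MOLAR = 10.0

# Relative solubility change of the solute at the solvent's cmax, per
# solvent, for the paper_like preset. Sign encodes soluble (+) vs
# insoluble (-) interactions; 0 encodes inert solvents.
_PAPER_LIKE_DELTA: dict[str, float] = {
    "Tyr": 0.25, "Trp": 0.30, "Phe": 0.20,        # aromatic: pi-pi stacking
    "Arg": 0.25,                                   # cation-pi
    "His": 0.15, "Pro": 1.00,                      # Pro acts as a hydrotrope at molar levels
    "Gly": 0.0, "Ser": 0.0, "Thr": 0.0, "Lys": 0.0,
    "Ala": -0.20, "Val": -0.20, "Leu": -0.20,
    "Ile": -0.20, "Met": -0.20, "Cys": -0.20,      # hydrophobic coprecipitation
    "Gln": -0.20, "Asn": -0.20,                    # amide
    "Glu": -0.30, "Asp": -0.30,                    # anionic repulsion, strongest insolubilizers
}

# Solute weights shaping the within-solvent ordering: Trp > Tyr > Phe in
# solubilizing solvents; Phe > Trp > Tyr (least to most affected) in
# insolubilizing solvents.
_SOLUTE_WEIGHT_POSITIVE = {"Trp": 1.25, "Tyr": 1.00, "Phe": 0.80}
_SOLUTE_WEIGHT_NEGATIVE = {"Tyr": 1.25, "Trp": 1.00, "Phe": 0.80}

PRESETS = ("paper_like", "null")


class DilutionError(ValueError):
    """No dilution from the ladder brings the absorbance into range."""


@dataclass(frozen=True)
class StandardCurve:
    """Linear absorbance-vs-concentration calibration for one solute."""

    solute: str
    wavelength: float
    slope: float          # absorbance per solubility unit
    intercept: float = 0.0
    valid_range: tuple[float, float] = (0.1, 1.0)

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("standard-curve slope must be positive")
        if not (260.0 <= self.wavelength <= 280.0):
            raise ValueError("quantification wavelength must lie in 260-280 nm")
        if not self.valid_range[0] < self.valid_range[1]:
            raise ValueError("valid_range must be a non-empty interval")


@dataclass
class AssayRecord:
    """One saturation-solubility measurement."""

    solute: str
    solvent: str
    conc: float           # solvent concentration, M
    replicate: int
    solubility: float     # same units as s0 (g per 100 mL by default)
    absorbance: float | None = None
    dilution: float = 1.0
    truncated: bool = False


@dataclass(frozen=True)
class Scenario:
    """Ground truth and noise/design parameters for a simulated assay."""

    true_psas: Mapping[tuple[str, str], float]  # (solute, solvent) -> slope, per M
    s0: Mapping[str, float]                     # solute -> water solubility
    cmax: Mapping[str, float]                   # solvent -> max usable conc, M
    noise_sd: float = 0.05                      # relative to s0
    nonlinearity: Mapping[tuple[str, str], float] = field(default_factory=dict)
    seed: int = 0
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        bad = [k for k, v in self.cmax.items() if v <= 0]
        if bad:
            raise ValueError(f"cmax must be positive; offending solvents: {bad}")
        bad = [k for k, v in self.s0.items() if v <= 0]
        if bad:
            raise ValueError(f"s0 must be positive; offending solutes: {bad}")

    @property
    def solutes(self) -> tuple[str, ...]:
        return tuple(self.s0)

    @property
    def solvents(self) -> tuple[str, ...]:
        return tuple(self.cmax)

    def truth(self, solute: str, solvent: str) -> float:
        return self.true_psas[(canonical_residue(solute), canonical_residue(solvent))]


@dataclass(frozen=True)
class Design:
    """Concentration-grid and replication design.

    ``n_conc`` points per solvent, evenly spaced up to that solvent's cmax.
    The 0 M (plain buffer) point anchors the water baseline and is included
    by default. Explicit per-solvent grids may be supplied instead.
    """

    n_conc: int = 5
    n_reps: int = 3
    include_zero: bool = True
    grids: Mapping[str, Sequence[float]] | None = None

    def grid_for(self, solvent: str, cmax: float) -> np.ndarray:
        if self.grids is not None and solvent in self.grids:
            grid = np.asarray(self.grids[solvent], dtype=float)
            if grid.max() > cmax:
                raise ValueError(
                    f"requested grid exceeds cmax for solvent {solvent}: "
                    f"{grid.max():g} M > {cmax:g} M"
                )
            if (grid < 0).any():
                raise ValueError(f"negative concentration in grid for solvent {solvent}")
            return np.sort(grid)
        if self.include_zero:
            return np.linspace(0.0, cmax, self.n_conc)
        return np.linspace(cmax / self.n_conc, cmax, self.n_conc)


def default_cmax(scale: float = 1.0) -> dict[str, float]:
    """Per-solvent maximum usable concentration, M.

    Derived from each solvent's aqueous-solubility entry in the packaged
    index table (taken as g per 100 mL) converted to molar units through
    the residue molar mass, then multiplied by ``scale``. Solvent maxima
    consequently span three orders of magnitude, from ~3 mM (Tyr) to
    ~11 M (Pro).
    """
    sol = load_index_set()["solubility_in_water"].values
    return {
        r: scale * sol[r] * G100ML_TO_MOLAR / MOLAR_MASS[r]
        for r in CANONICAL_RESIDUES
    }


def default_s0() -> dict[str, float]:
    """Aromatic-solute solubility in plain buffer (g per 100 mL)."""
    sol = load_index_set()["solubility_in_water"].values
    return {r: sol[r] for r in AROMATIC_RESIDUES}


def default_standard_curves() -> dict[str, StandardCurve]:
    """UV standard curves for the aromatic solutes.

    Slopes come from the molar extinction coefficients of the free amino
    acids at their absorption maxima (Trp 5500, Tyr 1490, Phe 195 per M per
    cm) converted to the g-per-100-mL solubility unit.
    """
    eps = {"Trp": (280.0, 5500.0), "Tyr": (275.0, 1490.0), "Phe": (260.0, 195.0)}
    return {
        r: StandardCurve(
            solute=r,
            wavelength=eps[r][0],
            slope=eps[r][1] * G100ML_TO_MOLAR / MOLAR_MASS[r],
        )
        for r in AROMATIC_RESIDUES
    }


def _paper_like_truth(cmax: Mapping[str, float]) -> dict[tuple[str, str], float]:
    truth: dict[tuple[str, str], float] = {}
    for solvent in CANONICAL_RESIDUES:
        delta = _PAPER_LIKE_DELTA[solvent]
        for solute in AROMATIC_RESIDUES:
            if delta > 0:
                w = _SOLUTE_WEIGHT_POSITIVE[solute]
            elif delta < 0:
                w = _SOLUTE_WEIGHT_NEGATIVE[solute]
            else:
                w = 0.0
            truth[(solute, solvent)] = delta * w / cmax[solvent]
    return truth


def make_scenario(preset: str, seed: int = 0, **overrides) -> Scenario:
    """Build a simulation scenario from a named preset.

    Presets
    -------
    ``paper_like``
        Sign structure of the measured interaction matrix: positive slopes
        for aromatic, Arg, His and Pro solvents (aromatic solvents, with
        their tiny cmax, carry the largest slopes); negative slopes for
        Glu/Asp (most negative), Gln/Asn and the hydrophobic solvents;
        zero for Gly, Ser, Thr and Lys. Within solubilizing solvents the
        solute order is Trp > Tyr > Phe.
    ``null``
        All true slopes zero (no interaction); useful as a negative control.

    Any :class:`Scenario` field may be overridden by keyword.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; available presets: {', '.join(PRESETS)}")
    cmax = overrides.pop("cmax", default_cmax())
    s0 = overrides.pop("s0", default_s0())
    if "true_psas" in overrides:
        truth = overrides.pop("true_psas")
    elif preset == "paper_like":
        truth = _paper_like_truth(cmax)
    else:
        truth = {(sol, sv): 0.0 for sv in cmax for sol in s0}
    return Scenario(true_psas=truth, s0=s0, cmax=cmax, seed=seed, name=preset, **overrides)


def simulate_assay(
    scenario: Scenario,
    design: Design | None = None,
    seed: int | None = None,
) -> list[AssayRecord]:
    """Draw one full simulated assay: every (solute, solvent) pair on its
    concentration grid, with replicate noise.

    The random stream is derived from ``seed`` (default: the scenario's
    seed); identical scenario + design + seed give identical records.
    Negative noise draws are truncated at 0 and flagged on the record.
    """
    design = design or Design()
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    records: list[AssayRecord] = []
    for solvent in scenario.solvents:
        grid = design.grid_for(solvent, scenario.cmax[solvent])
        for solute in scenario.solutes:
            s0 = scenario.s0[solute]
            psas = scenario.true_psas[(solute, solvent)]
            curv = scenario.nonlinearity.get((solute, solvent), 0.0)
            for c in grid:
                mean = s0 * (1.0 + psas * c + curv * c * c)
                noise = rng.normal(0.0, scenario.noise_sd * s0, size=design.n_reps)
                for rep in range(1, design.n_reps + 1):
                    s = mean + noise[rep - 1]
                    truncated = s < 0
                    records.append(
                        AssayRecord(
                            solute=solute,
                            solvent=solvent,
                            conc=float(c),
                            replicate=rep,
                            solubility=max(s, 0.0),
                            truncated=bool(truncated),
                        )
                    )
    return records


#: Dilution ladder used by the default policy: 1-2-5 decades.
_DILUTION_LADDER = tuple(
    f * 10.0 ** k for k in range(0, 7) for f in (1.0, 2.0, 5.0)
)


def observe_absorbance(
    records: Iterable[AssayRecord],
    curves: Mapping[str, StandardCurve],
    ladder: Sequence[float] = _DILUTION_LADDER,
) -> list[AssayRecord]:
    """Fill the absorbance field of each record through its standard curve.

    For each record the smallest dilution from ``ladder`` for which
    ``slope * solubility / dilution + intercept`` falls within the curve's
    valid absorbance range is used; the top of the range is treated as
    detector saturation and excluded. A zero-solubility record reads the
    curve intercept (blank) at dilution 1 when the intercept itself is in
    range.

    Raises
    ------
    DilutionError
        If no ladder dilution is feasible for a record.
    """
    out: list[AssayRecord] = []
    for rec in records:
        curve = curves[rec.solute]
        lo, hi = curve.valid_range
        if rec.solubility == 0.0:
            if lo <= curve.intercept < hi:
                out.append(replace(rec, absorbance=curve.intercept, dilution=1.0))
                continue
            raise DilutionError(
                f"zero-solubility record ({rec.solute} in {rec.solvent} at "
                f"{rec.conc:g} M) reads only the blank, outside the valid range"
            )
        for d in ladder:
            a = curve.slope * rec.solubility / d + curve.intercept
            if lo <= a < hi:
                out.append(replace(rec, absorbance=a, dilution=float(d)))
                break
        else:
            raise DilutionError(
                f"no feasible dilution for {rec.solute} in {rec.solvent} at "
                f"{rec.conc:g} M (solubility {rec.solubility:g})"
            )
    return out


_CSV_COLUMNS = ["solute", "solvent", "conc_M", "replicate", "solubility", "absorbance", "dilution"]


def records_to_frame(records: Iterable[AssayRecord]) -> pd.DataFrame:
    """Records as a DataFrame in the assay CSV schema."""
    return pd.DataFrame(
        [
            {
                "solute": r.solute,
                "solvent": r.solvent,
                "conc_M": r.conc,
                "replicate": r.replicate,
                "solubility": r.solubility,
                "absorbance": r.absorbance,
                "dilution": r.dilution,
            }
            for r in records
        ],
        columns=_CSV_COLUMNS,
    )


def frame_to_records(df: pd.DataFrame) -> list[AssayRecord]:
    """Inverse of :func:`records_to_frame` (absorbance may be empty)."""
    records = []
    for row in df.itertuples(index=False):
        absorbance = getattr(row, "absorbance", None)
        if absorbance is not None and pd.isna(absorbance):
            absorbance = None
        records.append(
            AssayRecord(
                solute=canonical_residue(row.solute),
                solvent=canonical_residue(row.solvent),
                conc=float(row.conc_M),
                replicate=int(row.replicate),
                solubility=float(row.solubility),
                absorbance=None if absorbance is None else float(absorbance),
                dilution=float(getattr(row, "dilution", 1.0)),
            )
        )
    return records


def write_assay_csv(records: Iterable[AssayRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_assay_csv(path: str | Path) -> list[AssayRecord]:
    return frame_to_records(pd.read_csv(path, float_precision="round_trip"))
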