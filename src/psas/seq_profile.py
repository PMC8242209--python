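"""Sliding-window index profiles of protein sequences.

Classic hydropathy-plot machinery generalized to any packaged or fitted
amino-acid scale: the score at a window center is the mean scale value
over the ``w`` residues of the window. Window centers are reported
1-based. Windows containing a residue outside the 20 canonical amino
acids (``X``, ``B`` ...) are skipped and their centers recorded, rather
than imputing a value for the unknown residue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .index_db import IndexSet
from .residues import ONE_TO_THREE

__all__ = ["FastaError", "SequenceProfile", "read_fasta", "profile", "profiles_to_frame"]


class FastaError(ValueError):
    """Malformed, empty or duplicate-id FASTA input."""


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read protein sequences from a FASTA file into an id -> sequence map.

    Characters outside the 20 canonical one-letter codes are kept but
    flagged with a warning (their windows are later skipped by
    :func:`profile`).

    Raises
    ------
    FastaError
        For an empty or non-FASTA file, or duplicate record ids.
    """
    path = Path(path)
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:
        raise FastaError(f"{path}: not a FASTA file ({exc})") from None
    if not records:
        raise FastaError(f"{path}: no FASTA records found (empty or malformed file)")
    out: dict[str, str] = {}
    for rec in records:
        if rec.id in out:
            raise FastaError(f"{path}: duplicate sequence id {rec.id!r}")
        seq = str(rec.seq).upper()
        unknown = sorted({ch for ch in seq if ch not in ONE_TO_THREE})
        if unknown:
            positions = [i + 1 for i, ch in enumerate(seq) if ch in unknown]
            warnings.warn(
                f"{rec.id}: non-canonical residues {unknown} at positions "
                f"{positions[:10]}{'...' if len(positions) > 10 else ''}",
                stacklevel=2,
            )
        out[rec.id] = seq
    return out


@dataclass
class SequenceProfile:
    """Windowed index profile of one sequence."""

    seq_id: str
    index_name: str
    window: int
    positions: np.ndarray   # 1-based window centers with a valid score
    scores: np.ndarray      # mean index value over each window
    skipped: list[int]      # centers of windows containing unknown residues

    def __len__(self) -> int:
        return len(self.positions)


def profile(
    sequence: str,
    index_set: IndexSet,
    index_name: str,
    window: int = 9,
    seq_id: str = "",
) -> SequenceProfile:
    """Sliding-window mean of an index over a sequence.

    ``window`` must be odd and no longer than the sequence; for a sequence
    of length L there are L - w + 1 windows, centered at 1-based positions
    (w+1)/2 ... L-(w-1)/2. With ``window=1`` the scores are the
    per-residue index values.
    """
    seq = sequence.upper()
    L = len(seq)
    w = int(window)
    if w < 1 or w % 2 == 0:
        raise ValueError(f"window must be a positive odd integer, got {window}")
    if w > L:
        raise ValueError(f"window {w} longer than sequence (length {L})")
    scale = index_set[index_name]

    values = np.empty(L)
    known = np.ones(L, dtype=bool)
    for i, ch in enumerate(seq):
        three = ONE_TO_THREE.get(ch)
        if three is None:
            known[i] = False
            values[i] = np.nan
        else:
            values[i] = scale.values[three]

    kernel = np.ones(w) / w
    # window means at centers; invalid where any residue in the window is unknown
    means = np.convolve(np.where(known, values, 0.0), kernel, mode="valid")
    ok = np.convolve(known.astype(float), np.ones(w), mode="valid") == w
    centers = np.arange((w + 1) // 2, L - (w - 1) // 2 + 1)

    return SequenceProfile(
        seq_id=seq_id,
        index_name=index_name,
        window=w,
        positions=centers[ok],
        scores=means[ok],
        skipped=[int(p) for p in centers[~ok]],
    )


def profiles_to_frame(profiles: list[SequenceProfile]):
    """Profiles as a tidy ``seq_id, position, score`` table."""
    import pandas as pd

    return pd.DataFrame(
        [
            {"seq_id": p.seq_id, "position": int(pos), "score": float(s)}
            for p in profiles
            for pos, s in zip(p.positions, p.scores)
        ],
        columns=["seq_id", "position", "score"],
    )
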