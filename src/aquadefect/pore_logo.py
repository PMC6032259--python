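"""Pore-lining residue identification and pore-logo frequency matrices.

A pore-logo is a sequence logo whose columns are not consecutive sequence
positions but the residues lining the channel, ordered geometrically along
the channel axis from the cytoplasmic to the extracellular side.  Residues
line the pore when at least one heavy atom comes within a probe margin of
the maximal-sphere surface of the pore profile.

Alignment handling goes through Bio.AlignIO objects; frequencies exclude
gaps from the denominator and information content is log2(20) - H (bits).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio.Align import MultipleSeqAlignment

from .pore_profiler import PoreProfile
from .structure import Residue, Structure

__all__ = [
    "PoreMapping",
    "LogoMatrix",
    "pore_lining_residues",
    "map_alignment_columns",
    "logo_frequencies",
    "position_of",
    "load_packaged_mapping",
]

AA_ORDER = list("ACDEFGHIKLMNPQRSTVWY")
MAX_INFO = float(np.log2(20.0))


@dataclass
class PoreMapping:
    """Ordered pore positions: (index from cytoplasmic side, residue number,
    alignment column).  Indices are contiguous from 1."""

    positions: List[Tuple[int, int, int]]
    reference: str = ""

    def __post_init__(self) -> None:
        idx = [p[0] for p in self.positions]
        if idx != list(range(1, len(idx) + 1)):
            raise ValueError("pore positions must be contiguous from 1")

    @property
    def n_positions(self) -> int:
        return len(self.positions)

    def residue_numbers(self) -> List[int]:
        return [p[1] for p in self.positions]

    def columns(self) -> List[int]:
        return [p[2] for p in self.positions]


@dataclass
class LogoMatrix:
    """Per-position amino-acid frequencies and information content."""

    frequencies: pd.DataFrame        # index = pore position, columns = 20 aa
    information: pd.Series           # bits per position (NaN where undefined)

    def to_tsv(self, path) -> None:
        out = self.frequencies.copy()
        out["information"] = self.information
        out.to_csv(path, sep="\t", index_label="position")


def pore_lining_residues(structure: Structure, profile: PoreProfile,
                         margin: float = 1.4) -> List[Residue]:
    """Residues with a heavy atom within *margin* of the pore surface.

    An atom at distance d from a profile sphere centre lines the pore when
    | d - (radius + vdw) | <= margin for some non-open slice; residues are
    ordered by the axial coordinate of their closest-approach atom,
    cytoplasmic side first, ties broken by residue number.
    """
    interior = profile.interior()
    if not interior.any():
        raise ValueError("profile has no interior slices")
    centers = profile.centers[interior]
    radii = profile.radius[interior]
    ordered: List[Tuple[float, int, Residue]] = []
    for res in structure.residues():
        best_gap, best_z = np.inf, None
        for atom in res.atoms:
            d = np.linalg.norm(centers - atom.xyz, axis=1)
            gap = np.abs(d - (radii + atom.vdw))
            k = int(np.argmin(gap))
            if gap[k] < best_gap:
                best_gap = float(gap[k])
                best_z = float(profile.axis.to_frame(atom.xyz)[2])
        if best_gap <= margin:
            ordered.append((best_z, res.number, res))
    # z quantized to 1e-6 Å so exact height ties break by residue number
    # regardless of floating-point noise from rigid transforms
    ordered.sort(key=lambda t: (round(t[0], 6), t[1]))
    return [r for _, _, r in ordered]


def _reference_columns(alignment: MultipleSeqAlignment, reference: str,
                       ref_start: int = 1) -> Dict[int, int]:
    """Map reference residue numbers to 1-based alignment columns."""
    for rec in alignment:
        if rec.id == reference:
            mapping: Dict[int, int] = {}
            number = ref_start - 1
            for col, letter in enumerate(str(rec.seq), start=1):
                if letter != "-":
                    number += 1
                    mapping[number] = col
            return mapping
    raise KeyError(f"reference sequence {reference!r} not in alignment")


def map_alignment_columns(ordered_residues: Sequence[Residue],
                          alignment: MultipleSeqAlignment,
                          reference: str, ref_start: int = 1) -> PoreMapping:
    """Pair each pore position with its alignment column via the reference.

    Residue numbers are interpreted as positions in the ungapped reference
    sequence (offset by *ref_start*).  A residue absent from the reference
    is an error naming the residue.
    """
    colmap = _reference_columns(alignment, reference, ref_start)
    positions = []
    for idx, res in enumerate(ordered_residues, start=1):
        if res.number not in colmap:
            raise KeyError(
                f"residue {res.resname}{res.number} not covered by reference "
                f"{reference!r}"
            )
        positions.append((idx, res.number, colmap[res.number]))
    return PoreMapping(positions=positions, reference=reference)


def logo_frequencies(alignment: MultipleSeqAlignment, mapping: PoreMapping,
                     subset: Optional[Sequence[str]] = None) -> LogoMatrix:
    """Amino-acid frequencies of the mapped columns over *subset* sequences.

    Gaps are excluded from the denominator; a column that is entirely
    gapped gets a NaN frequency row and NaN information.
    """
    if subset is None:
        subset = [rec.id for rec in alignment]
    if len(subset) == 0:
        raise ValueError("subset must be non-empty")
    rows = {rec.id: str(rec.seq) for rec in alignment}
    missing = [s for s in subset if s not in rows]
    if missing:
        raise KeyError(f"sequences not in alignment: {missing}")
    freq = pd.DataFrame(0.0, index=[p[0] for p in mapping.positions],
                        columns=AA_ORDER)
    info = pd.Series(np.nan, index=freq.index, dtype=float)
    for idx, _resnum, col in mapping.positions:
        letters = [rows[s][col - 1] for s in subset]
        letters = [l for l in letters if l != "-"]
        if not letters:
            freq.loc[idx] = np.nan
            continue
        counts = pd.Series(letters).value_counts()
        for aa, c in counts.items():
            if aa in freq.columns:
                freq.loc[idx, aa] = c / len(letters)
        p = freq.loc[idx].to_numpy()
        p = p[p > 0]
        info.loc[idx] = MAX_INFO + float(np.sum(p * np.log2(p)))
    return LogoMatrix(frequencies=freq, information=info)


def position_of(mapping: PoreMapping, residue_number: int) -> Optional[int]:
    """1-based pore position of *residue_number*; None when not lining."""
    for idx, num, _col in mapping.positions:
        if num == residue_number:
            return idx
    return None


def load_packaged_mapping() -> PoreMapping:
    """Load the packaged 51-position pore mapping (synthetic stand-in).

    The file is a constructed surrogate consistent with the documented
    residue/position anchor pairs for human AQP2 (see the file header);
    it is not a transcription of a published figure.
    """
    ref = resources.files("aquadefect.data").joinpath("pore_mapping_synthetic.tsv")
    positions = []
    with ref.open() as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("position"):
                continue
            idx, resnum, col = line.split("\t")[:3]
            positions.append((int(idx), int(resnum), int(col)))
    return PoreMapping(positions=positions, reference="AQP2")
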