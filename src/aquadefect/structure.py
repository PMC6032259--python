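"""Coordinate model for channel-protein analysis.

A :class:`Structure` is an ordered set of chains of :class:`Residue` objects
holding heavy-atom coordinates with van-der-Waals radii (Bondi set) attached
at load time.  Hydrogens are discarded everywhere: the crystallographic
inputs this pipeline consumes do not resolve them, and all steric criteria
downstream are defined on heavy atoms.

PDB reading/writing is delegated to gemmi; the containers here add what the
analyses need (vdW radii, topology labels, flat coordinate arrays) without
carrying the full crystallographic bookkeeping.
"""

from __future__ import annotations

import copy as _copy
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, List, Optional, Tuple

import gemmi
import numpy as np
import yaml

from .geometry import rotation_about_axis, unit

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "TopologyAnnotation",
    "BONDI_VDW",
    "AA_3TO1",
    "AA_1TO3",
    "read_pdb",
    "write_pdb",
    "build_c4_assembly",
    "annotate_topology",
    "vdw_radius",
]

# Bondi van-der-Waals radii, Å.  Heavy elements seen in protein structures.
BONDI_VDW: Dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
}
_DEFAULT_VDW = 1.70

AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA_1TO3 = {v: k for k, v in AA_3TO1.items()}

BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}


def vdw_radius(element: str) -> float:
    """Bondi radius for *element*; unknown elements fall back to 1.7 Å."""
    el = element.strip().upper()
    if el not in BONDI_VDW:
        warnings.warn(f"no vdW radius for element {element!r}; using {_DEFAULT_VDW} Å")
        return _DEFAULT_VDW
    return BONDI_VDW[el]


@dataclass
class Atom:
    name: str
    element: str
    xyz: np.ndarray
    vdw: float
    is_backbone: bool

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if self.vdw <= 0:
            raise ValueError(f"non-positive vdW radius for atom {self.name}")


@dataclass
class Residue:
    aa: str                 # 1-letter code; 'X' for non-standard
    number: int             # author numbering
    atoms: List[Atom]
    chain: str
    icode: str = ""
    label: str = ""         # structural-element label set by annotate_topology
    resname: str = ""       # 3-letter name (kept for non-standard residues)

    def __post_init__(self) -> None:
        if not self.resname:
            self.resname = AA_1TO3.get(self.aa, "UNK")

    @property
    def key(self) -> Tuple[str, int, str]:
        return (self.chain, self.number, self.icode)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"atom {name} not in {self.chain}/{self.resname}{self.number}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def side_chain_atoms(self) -> List[Atom]:
        return [a for a in self.atoms if not a.is_backbone]

    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms])

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Residue {self.chain}/{self.resname}{self.number}{self.icode}>"


class Structure:
    """Ordered chains of residues; assembly is 'monomer' or 'tetramer'."""

    def __init__(self, chains: Dict[str, List[Residue]], assembly: str = "monomer",
                 source: str = "synthetic"):
        self.chains: Dict[str, List[Residue]] = dict(chains)
        self.assembly = assembly
        self.source = source
        seen = set()
        for cid, residues in self.chains.items():
            for r in residues:
                if r.key in seen:
                    raise ValueError(f"duplicate residue key {r.key}")
                seen.add(r.key)
                r.chain = cid

    # -- lookups ----------------------------------------------------------
    def residues(self) -> Iterator[Residue]:
        for residues in self.chains.values():
            yield from residues

    def residue(self, chain: str, number: int, icode: str = "") -> Residue:
        for r in self.chains[chain]:
            if r.number == number and r.icode == icode:
                return r
        raise KeyError(f"residue {chain}/{number}{icode} not found")

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues())

    def flat_atoms(self):
        """Return (coords [N,3], vdw [N], owners [N] list of (Residue, Atom))."""
        coords, vdw, owners = [], [], []
        for r in self.residues():
            for a in r.atoms:
                coords.append(a.xyz)
                vdw.append(a.vdw)
                owners.append((r, a))
        return np.array(coords, dtype=float), np.array(vdw, dtype=float), owners

    # -- transforms -------------------------------------------------------
    def copy(self) -> "Structure":
        return _copy.deepcopy(self)

    def transform(self, rot: np.ndarray, trans: np.ndarray) -> None:
        """In-place rigid transform x -> rot @ x + trans."""
        rot = np.asarray(rot, float)
        trans = np.asarray(trans, float)
        for r in self.residues():
            for a in r.atoms:
                a.xyz = rot @ a.xyz + trans


# ---------------------------------------------------------------------------
# topology annotation
# ---------------------------------------------------------------------------

@dataclass
class TopologyAnnotation:
    """Structural-element annotation of one channel monomer.

    helix_ranges/loops map labels ("H1".."H6", "HB", "HE", "loop A", ...) to
    inclusive (start, end) author-numbered intervals.  c_tail_start marks the
    first cytoplasmic C-tail residue; npa_residues and arR_residues locate the
    two channel constrictions; phosphosites list regulatory Ser/Thr positions.
    """

    helix_ranges: Dict[str, Tuple[int, int]] = field(default_factory=dict)
    loops: Dict[str, Tuple[int, int]] = field(default_factory=dict)
    c_tail_start: Optional[int] = None
    phosphosites: List[int] = field(default_factory=list)
    npa_residues: List[int] = field(default_factory=list)
    arR_residues: List[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        intervals = list(self.helix_ranges.values()) + list(self.loops.values())
        for s, e in intervals:
            if s > e:
                raise ValueError(f"inverted interval ({s}, {e})")
        ordered = sorted(intervals)
        for (s1, e1), (s2, e2) in zip(ordered, ordered[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping intervals ({s1},{e1}) and ({s2},{e2})")
        if self.c_tail_start is not None and self.helix_ranges:
            last = max(e for _, e in self.helix_ranges.values())
            if self.c_tail_start <= last:
                raise ValueError("c_tail_start must lie past the last helix")

    def label_of(self, number: int) -> str:
        if self.c_tail_start is not None and number >= self.c_tail_start:
            return "C-ter"
        for lab, (s, e) in self.helix_ranges.items():
            if s <= number <= e:
                return lab
        for lab, (s, e) in self.loops.items():
            if s <= number <= e:
                return lab
        return "other"

    @classmethod
    def from_yaml(cls, path) -> "TopologyAnnotation":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            helix_ranges={k: tuple(v) for k, v in raw.get("helix_ranges", {}).items()},
            loops={k: tuple(v) for k, v in raw.get("loops", {}).items()},
            c_tail_start=raw.get("c_tail_start"),
            phosphosites=list(raw.get("phosphosites", [])),
            npa_residues=list(raw.get("npa_residues", [])),
            arR_residues=list(raw.get("arR_residues", [])),
        )

    def to_yaml(self, path) -> None:
        data = {
            "helix_ranges": {k: list(v) for k, v in self.helix_ranges.items()},
            "loops": {k: list(v) for k, v in self.loops.items()},
            "c_tail_start": self.c_tail_start,
            "phosphosites": self.phosphosites,
            "npa_residues": self.npa_residues,
            "arR_residues": self.arR_residues,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)


def steric_exclusions(structure: Structure, residue: Residue):
    """Inter-residue atom pairs of *residue* exempt from steric scoring.

    Returns a set of (atom_name, other_residue_key, other_atom_name).
    Covalent geometry between sequence neighbours is invariant under point
    mutation and sits closer than vdW contact by construction (peptide
    bond, 1-3/1-4 pairs, and the carbonyl O(i)...C(i+1) approach of
    helices), so all backbone-backbone pairs of adjacent residues are
    excluded, plus the 1-4 pairs that involve CB and the proline CD-N
    attachment.
    """
    excl = set()
    if residue.aa == "X":
        return excl  # pseudo-residues carry no peptide connectivity
    chain = structure.chains[residue.chain]
    idx = next(i for i, r in enumerate(chain) if r.key == residue.key)
    bb = ("N", "CA", "C", "O", "OXT")
    for step in (-1, 1):
        j = idx + step
        if not (0 <= j < len(chain)):
            continue
        other = chain[j]
        if other.aa == "X":
            continue
        if abs(other.number - residue.number) > 1 and other.icode == residue.icode:
            continue  # chain break: not covalently linked
        for a in bb:
            for b in bb:
                excl.add((a, other.key, b))
        if step == -1:
            excl.add(("CB", other.key, "C"))
            excl.add(("N", other.key, "CB"))
            if residue.aa == "P":
                for b in ("C", "CA", "O"):
                    excl.add(("CD", other.key, b))
        else:
            excl.add(("CB", other.key, "N"))
            if other.aa == "P":
                for a in ("C", "CA", "O"):
                    excl.add((a, other.key, "CD"))
            excl.add(("C", other.key, "CB"))
    return excl


def annotate_topology(structure: Structure, annotation: TopologyAnnotation) -> Structure:
    """Label every residue of *structure* with its structural element.

    Raises if an annotated interval falls entirely outside the structure.
    Labelling is applied per chain (identical monomer annotation for all
    chains of an assembly).  Returns the same structure, mutated.
    """
    for cid, residues in structure.chains.items():
        numbers = {r.number for r in residues}
        for lab, (s, e) in {**annotation.helix_ranges, **annotation.loops}.items():
            if not any(n in numbers for n in range(s, e + 1)):
                raise ValueError(f"annotated interval {lab} ({s}-{e}) outside chain {cid}")
        for r in residues:
            r.label = annotation.label_of(r.number)
    structure.annotation = annotation  # type: ignore[attr-defined]
    return structure


# ---------------------------------------------------------------------------
# PDB I/O (gemmi-backed)
# ---------------------------------------------------------------------------

def read_pdb(path) -> Structure:
    """Load heavy atoms of all ATOM records from a PDB file.

    Hydrogens and waters are discarded; for alternate locations the
    highest-occupancy conformer is kept.  Standard residues missing a CA
    trigger a warning but are retained.
    """
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    st.remove_alternative_conformations()
    st.remove_hydrogens()
    st.remove_waters()
    model = st[0]
    chains: Dict[str, List[Residue]] = {}
    for ch in model:
        residues: List[Residue] = []
        for res in ch:
            if res.name == "HOH":
                continue
            atoms = []
            for at in res:
                if at.element.name.upper() == "H":
                    continue
                el = at.element.name.upper()
                atoms.append(
                    Atom(
                        name=at.name,
                        element=el,
                        xyz=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        vdw=vdw_radius(el),
                        is_backbone=at.name in BACKBONE_NAMES,
                    )
                )
            if not atoms:
                continue
            aa = AA_3TO1.get(res.name, "X")
            if aa != "X" and not any(a.name == "CA" for a in atoms):
                warnings.warn(
                    f"standard residue {res.name}{res.seqid.num} in chain "
                    f"{ch.name} lacks a CA atom"
                )
            residues.append(
                Residue(
                    aa=aa,
                    number=res.seqid.num,
                    icode=(res.seqid.icode or "").strip(),
                    atoms=atoms,
                    chain=ch.name,
                    resname=res.name,
                )
            )
        if residues:
            chains[ch.name] = residues
    assembly = "tetramer" if len(chains) == 4 else "monomer"
    return Structure(chains, assembly=assembly, source=Path(str(path)).stem)


def write_pdb(structure: Structure, path) -> None:
    """Write *structure* as a PDB file (coordinates to 0.001 Å)."""
    if len(set(structure.chains)) != len(structure.chains):  # pragma: no cover
        raise ValueError("chain id collision")
    st = gemmi.Structure()
    st.name = structure.source
    model = gemmi.Model("1")
    for cid, residues in structure.chains.items():
        ch = gemmi.Chain(cid)
        for r in residues:
            gr = gemmi.Residue()
            gr.name = r.resname
            gr.seqid = gemmi.SeqId(r.number, r.icode or " ")
            for a in r.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element.capitalize())
                ga.pos = gemmi.Position(*a.xyz)
                ga.occ = 1.0
                ga.b_iso = 0.0
                gr.add_atom(ga)
            ch.add_residue(gr)
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    doc = st.make_pdb_string()
    Path(str(path)).write_text(doc)


def build_c4_assembly(monomer: Structure, axis=(0.0, 0.0, 1.0),
                      origin=(0.0, 0.0, 0.0)) -> Structure:
    """Assemble a C4 homotetramer from a single-chain monomer.

    The four chains are related by successive 90° right-handed rotations
    about the line through *origin* along *axis* and are renamed A..D.
    Intra-monomer distances are preserved exactly (pure rotation).
    """
    if len(monomer.chains) != 1:
        raise ValueError("C4 assembly requires a single-chain monomer")
    axis = unit(np.asarray(axis, dtype=float))
    origin = np.asarray(origin, dtype=float)
    chains: Dict[str, List[Residue]] = {}
    ids = ["A", "B", "C", "D"]
    (src_residues,) = monomer.chains.values()
    for k, cid in enumerate(ids):
        rot = rotation_about_axis(axis, 90.0 * k)
        residues = []
        for r in src_residues:
            atoms = [
                Atom(a.name, a.element, rot @ (a.xyz - origin) + origin,
                     a.vdw, a.is_backbone)
                for a in r.atoms
            ]
            residues.append(Residue(aa=r.aa, number=r.number, icode=r.icode,
                                    atoms=atoms, chain=cid, resname=r.resname,
                                    label=r.label))
        chains[cid] = residues
    out = Structure(chains, assembly="tetramer", source=monomer.source)
    if hasattr(monomer, "annotation"):
        out.annotation = monomer.annotation  # type: ignore[attr-defined]
    return out
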