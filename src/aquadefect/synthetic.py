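"""Synthetic structures, alignments and variant tables with known ground truth.

These generators build geometric test objects — ideal α-helices, channel
walls with a prescribed radius profile, C4 helix-bundle "channels" — that
exercise every pipeline stage without any experimental input.  They make no
attempt at physical realism beyond ideal covalent geometry; each generator
is deterministic under a fixed seed and, where there is a planted ground
truth, returns it alongside the structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .geometry import place_atom, rotation_about_axis, unit
from .sidechains import build_side_chain
from .structure import Atom, Residue, Structure, vdw_radius

__all__ = [
    "ChannelSpec",
    "make_ideal_helix",
    "make_channel_wall",
    "make_bundle_channel",
    "make_toy_alignment",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

# ideal backbone internal coordinates (trans peptide, α-helical torsions)
_PHI, _PSI, _OMEGA = -57.0, -47.0, 180.0
_B_CN, _B_NCA, _B_CAC = 1.329, 1.458, 1.525
_A_CACN, _A_CNCA, _A_NCAC = 116.2, 121.7, 111.2


@dataclass
class ChannelSpec:
    """Wall-of-pseudo-atoms channel: radius profile, extent, packing."""

    wall_radius_fn: Callable[[float], float]
    z_range: Tuple[float, float] = (-15.0, 15.0)
    atom_density: float = 1.0        # atoms per Å² of wall surface
    atom_vdw: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.atom_density <= 0:
            raise ValueError("atom_density must be positive")
        z0, z1 = self.z_range
        for z in np.linspace(z0, z1, 64):
            if self.wall_radius_fn(float(z)) <= self.atom_vdw:
                raise ValueError("wall radius must exceed atom_vdw everywhere")


def make_ideal_helix(n_res: int, sequence: Optional[str] = None,
                     placement: Optional[Tuple[np.ndarray, np.ndarray]] = None,
                     chain: str = "A", start_number: int = 1,
                     chis: Sequence[float] = (180.0, 180.0, 180.0, 180.0)) -> Structure:
    """Build an ideal α-helix (φ=-57°, ψ=-47°) with template side chains.

    The helix is centred at the origin with its principal axis along +z;
    *placement* = (rotation, translation) is applied afterwards.  Default
    sequence is poly-alanine.
    """
    if n_res < 4:
        raise ValueError("need at least 4 residues for a helix")
    seq = sequence if sequence is not None else "A" * n_res
    if len(seq) != n_res:
        raise ValueError("sequence length must equal n_res")
    for aa in seq:
        if aa not in AA_ALPHABET:
            raise ValueError(f"unknown residue letter {aa!r}")

    # backbone by sequential natural extension
    bb: List[Dict[str, np.ndarray]] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_B_NCA, 0.0, 0.0])
    ang = np.radians(_A_NCAC)
    c0 = ca0 + _B_CAC * np.array([-np.cos(ang), np.sin(ang), 0.0])
    bb.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_res):
        prev = bb[-1]
        n = place_atom(prev["N"], prev["CA"], prev["C"], _B_CN, _A_CACN, _PSI)
        ca = place_atom(prev["CA"], prev["C"], n, _B_NCA, _A_CNCA, _OMEGA)
        c = place_atom(prev["C"], n, ca, _B_CAC, _A_NCAC, _PHI)
        bb.append({"N": n, "CA": ca, "C": c})
    # carbonyl oxygens (anti to the next N; last residue anti to its own N)
    for i, frame in enumerate(bb):
        if i + 1 < n_res:
            frame["O"] = place_atom(bb[i + 1]["N"], frame["CA"], frame["C"],
                                    1.231, 120.8, 180.0)
        else:
            frame["O"] = place_atom(frame["N"], frame["CA"], frame["C"],
                                    1.231, 120.8, _PSI + 180.0)

    # centre on origin, principal CA axis -> +z
    cas = np.array([f["CA"] for f in bb])
    centroid = cas.mean(axis=0)
    u, s, vt = np.linalg.svd(cas - centroid)
    axis = vt[0]
    if axis[2] < 0 or (axis[2] == 0 and np.dot(axis, cas[-1] - cas[0]) < 0):
        axis = -axis
    if np.dot(axis, cas[-1] - cas[0]) < 0:
        axis = -axis
    # rotation taking axis -> z
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    if np.linalg.norm(v) < 1e-12:
        rot = np.eye(3)
    else:
        angle = np.degrees(np.arccos(np.clip(np.dot(axis, z), -1, 1)))
        rot = rotation_about_axis(v, angle)

    residues: List[Residue] = []
    for i, (frame, aa) in enumerate(zip(bb, seq)):
        atoms = []
        for name in ("N", "CA", "C", "O"):
            el = name[0]
            atoms.append(Atom(name, el, frame[name], vdw_radius(el), True))
        for name, el, xyz in build_side_chain(frame["N"], frame["CA"], frame["C"],
                                              aa, chis):
            atoms.append(Atom(name, el, xyz, vdw_radius(el), False))
        residues.append(Residue(aa=aa, number=start_number + i, atoms=atoms,
                                chain=chain))
    st = Structure({chain: residues}, assembly="monomer", source="synthetic")
    st.transform(rot, -rot @ centroid)
    if placement is not None:
        prot, ptrans = placement
        st.transform(np.asarray(prot, float), np.asarray(ptrans, float))
    return st


def make_channel_wall(spec: ChannelSpec) -> Tuple[Structure, Dict]:
    """Tile pseudo-atoms on the surface r = wall_radius_fn(z) around the z axis.

    Returns (structure, ground_truth); the expected pore radius at height z
    is wall_radius_fn(z) - atom_vdw.  Raises when the packing leaves holes
    larger than the atom radius.
    """
    s = 1.0 / np.sqrt(spec.atom_density)    # mean inter-atom spacing on the wall
    if s - spec.atom_vdw > spec.atom_vdw:
        raise ValueError("atom_density too low to close the wall")
    z0, z1 = spec.z_range
    zs = np.arange(z0, z1 + 1e-9, s)
    residues: List[Residue] = []
    for ring_idx, z in enumerate(zs):
        r = spec.wall_radius_fn(float(z))
        n = max(int(np.ceil(2 * np.pi * r / s)), 3)
        phase = (ring_idx % 2) * np.pi / n   # stagger alternate rings
        atoms = []
        for j in range(n):
            t = 2 * np.pi * j / n + phase
            xyz = np.array([r * np.cos(t), r * np.sin(t), z])
            atoms.append(Atom("C", "C", xyz, spec.atom_vdw, False))
        residues.append(Residue(aa="X", number=ring_idx + 1, atoms=atoms,
                                chain="W", resname="UNK"))
    st = Structure({"W": residues}, assembly="monomer", source="synthetic")
    truth_z = np.arange(z0, z1 + 1e-9, 0.5)
    truth = {
        "z": [float(z) for z in truth_z],
        "expected_radius": [float(spec.wall_radius_fn(float(z)) - spec.atom_vdw)
                            for z in truth_z],
        "atom_vdw": spec.atom_vdw,
    }
    return st, truth


def make_bundle_channel(n_helices: int, ring_radius: float, length: int,
                        sequences: Optional[Sequence[str]] = None,
                        facing_residue: Optional[Tuple[int, int, str]] = None,
                        chain: str = "A", z_stagger: float = 0.0) -> Structure:
    """Vertical α-helix bundle around the z axis: a toy channel monomer.

    Helix *h* occupies residue numbers h*100+1 .. h*100+length in a single
    chain, so per-helix topology annotation is straightforward.  Helices
    are staggered vertically by *z_stagger* Å each (mean-centred), which
    breaks the exact height degeneracy between equivalent residues of
    different helices.  When *facing_residue* = (helix_index,
    residue_offset, aa) is given, that residue is substituted into the
    sequence and its helix is spun about its own axis so the residue's CB
    points at the bundle axis.
    """
    if n_helices < 3:
        raise ValueError("need at least 3 helices")
    gap = 2 * ring_radius * np.sin(np.pi / n_helices)
    if gap < 7.0:
        raise ValueError("ring_radius too small: helices would overlap")
    if sequences is None:
        sequences = ["A" * length] * n_helices
    sequences = [list(s) for s in sequences]
    if facing_residue is not None:
        h_idx, offset, aa = facing_residue
        sequences[h_idx][offset] = aa
    residues: List[Residue] = []
    for h in range(n_helices):
        seq = "".join(sequences[h])
        helix = make_ideal_helix(length, seq, chain=chain,
                                 start_number=h * 100 + 1)
        theta = 360.0 * h / n_helices
        dz = z_stagger * (h - (n_helices - 1) / 2.0)
        pos = np.array([ring_radius * np.cos(np.radians(theta)),
                        ring_radius * np.sin(np.radians(theta)), dz])
        spin = 0.0
        if facing_residue is not None and h == facing_residue[0]:
            # spin so the planted residue's CB faces the bundle axis
            target = facing_residue[1] + h * 100 + 1
            best, best_d = 0.0, np.inf
            for cand in np.arange(0.0, 360.0, 5.0):
                probe = helix.copy()
                probe.transform(rotation_about_axis([0, 0, 1], cand), np.zeros(3))
                probe.transform(np.eye(3), pos)
                res = probe.residue(chain, target)
                anchor = res.atom("CB").xyz if res.has_atom("CB") else res.atom("CA").xyz
                d = float(np.linalg.norm(anchor[:2]))
                if d < best_d:
                    best_d, best = d, cand
            spin = best
        helix.transform(rotation_about_axis([0, 0, 1], spin), np.zeros(3))
        helix.transform(np.eye(3), pos)
        (chain_res,) = helix.chains.values()
        residues.extend(chain_res)
    return Structure({chain: residues}, assembly="monomer", source="synthetic")


def make_interface_tetramer(ring_radius: float = 12.0, length: int = 18,
                            spin: float = 60.0,
                            interface_aa: str = "L") -> Structure:
    """C4 tetramer of a two-helix unit with a planted interface residue.

    Each monomer is two parallel helices (residues 1-length and
    101-100+length) on a circle of *ring_radius*; the C4 assembly closes an
    eight-helix ring.  Residue 100+9 carries *interface_aa* spun so its
    side chain reaches across the monomer-monomer interface: with leucine
    it forms inter-monomer hydrophobic contacts without any vdW overlap,
    so shortening it (e.g. L->V) is a pure packing loss — the planted
    ground truth for the tetramer-assembly defect category.
    """
    helices: List[Residue] = []
    for k, (ang, start) in enumerate(((0.0, 1), (45.0, 101))):
        seq = ["A"] * length
        if k == 1:
            seq[8] = interface_aa
        h = make_ideal_helix(length, "".join(seq), start_number=start)
        if k == 1:
            h.transform(rotation_about_axis([0.0, 0.0, 1.0], spin), np.zeros(3))
        pos = ring_radius * np.array([np.cos(np.radians(ang)),
                                      np.sin(np.radians(ang)), 0.0])
        h.transform(np.eye(3), pos)
        (res,) = h.chains.values()
        helices.extend(res)
    monomer = Structure({"A": helices}, assembly="monomer", source="synthetic")
    from .structure import build_c4_assembly

    return build_c4_assembly(monomer)


def make_tailed_bundle(n_helices: int = 6, ring_radius: float = 9.0,
                       length: int = 18,
                       tail_sequence: str = "AAARASAAAA",
                       tail_start: int = 701) -> Structure:
    """Helix bundle plus a detached C-tail segment below the channel.

    The tail (default ``AAARASAAAA`` at numbers 701-710: Arg at 704, Ser
    at 706) sits 25 Å below the bundle, mimicking a cytoplasmic regulatory
    tail carrying a phosphosite — the planted ground truth for the
    signal-loss defect category.
    """
    bundle = make_bundle_channel(n_helices, ring_radius, length)
    tail = make_ideal_helix(len(tail_sequence), tail_sequence,
                            start_number=tail_start)
    tail.transform(np.eye(3), np.array([ring_radius + 4.0, 0.0, -25.0]))
    (tail_res,) = tail.chains.values()
    residues = list(bundle.chains["A"]) + tail_res
    return Structure({"A": residues}, assembly="monomer", source="synthetic")


def make_toy_alignment(n_seqs: int, length: int,
                       conserved_columns: Sequence[int], seed: int = 0,
                       conserved_aa: Optional[Dict[int, str]] = None
                       ) -> MultipleSeqAlignment:
    """Random alignment with fully conserved columns planted.

    *conserved_columns* are 1-based; each conserved column carries a single
    residue across all sequences (chosen from the seed unless pinned via
    *conserved_aa*).  Other columns are i.i.d. uniform over the 20 residues.
    """
    cols = set(conserved_columns)
    if not cols <= set(range(1, length + 1)):
        raise ValueError("conserved_columns out of range")
    rng = np.random.default_rng(seed)
    pinned = dict(conserved_aa or {})
    for c in sorted(cols):
        pinned.setdefault(c, AA_ALPHABET[rng.integers(20)])
    rows = []
    for i in range(n_seqs):
        letters = [AA_ALPHABET[k] for k in rng.integers(0, 20, size=length)]
        for c, aa in pinned.items():
            letters[c - 1] = aa
        rows.append(SeqRecord(Seq("".join(letters)), id=f"seq{i + 1}",
                              description=""))
    return MultipleSeqAlignment(rows)
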