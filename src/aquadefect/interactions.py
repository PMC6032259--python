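"""Residue-residue interaction analysis: contacts, clashes, salt bridges.

Definitions (heavy atoms only; hydrogens are never present):

* contact      — any heavy-atom pair within the contact cutoff (8 Å default,
                 the standard contact-map criterion);
* hydrophobic  — an apolar carbon/sulfur pair within 4.5 Å;
* salt bridge  — charged-group N/O pair of oppositely charged side chains
                 within 4.0 Å;
* clash        — vdW overlap (r_i + r_j - d) of at least the clash
                 threshold, excluding covalently bonded 1-2/1-3 pairs.

Scope is intra- or inter-monomer according to whether the chains differ.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.spatial import cKDTree

from .mutator import MutationSpec
from .structure import Residue, Structure, TopologyAnnotation, steric_exclusions

__all__ = [
    "Contact",
    "ContactDiff",
    "contact_map",
    "detect_clashes",
    "diff_contacts",
    "salt_bridges",
    "proline_in_helix",
    "CONTACT_CUTOFF",
    "HYDROPHOBIC_CUTOFF",
    "SALT_BRIDGE_CUTOFF",
]

CONTACT_CUTOFF = 8.0
HYDROPHOBIC_CUTOFF = 4.5
SALT_BRIDGE_CUTOFF = 4.0
CLASH_THRESHOLD = 0.3

ResKey = Tuple[str, int, str]

# apolar side-chain atoms: carbons/sulfurs not bonded to N or O
APOLAR_ATOMS: Dict[str, Tuple[str, ...]] = {
    "A": ("CB",),
    "V": ("CB", "CG1", "CG2"),
    "L": ("CB", "CG", "CD1", "CD2"),
    "I": ("CB", "CG1", "CG2", "CD1"),
    "M": ("CB", "CG", "SD", "CE"),
    "F": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "W": ("CB", "CG", "CD2", "CE3", "CZ2", "CZ3", "CH2"),
    "Y": ("CB", "CG", "CD1", "CD2", "CE1", "CE2"),
    "P": ("CB", "CG"),
    "C": ("CB", "SG"),
    "T": ("CG2",),
    "K": ("CB", "CG", "CD"),
    "R": ("CB", "CG"),
    "E": ("CB", "CG"),
    "Q": ("CB", "CG"),
    "D": ("CB",),
    "N": ("CB",),
    "H": ("CB",),
    "S": (),
    "G": (),
}

# charged-group atoms for salt bridges
POSITIVE_ATOMS: Dict[str, Tuple[str, ...]] = {
    "R": ("NH1", "NH2", "NE"),
    "K": ("NZ",),
    "H": ("ND1", "NE2"),
}
NEGATIVE_ATOMS: Dict[str, Tuple[str, ...]] = {
    "D": ("OD1", "OD2"),
    "E": ("OE1", "OE2"),
}


@dataclass(frozen=True)
class Contact:
    res_a: ResKey
    res_b: ResKey
    min_dist: float
    kind: str                  # contact | hydrophobic | salt_bridge | clash
    scope: str                 # intra_monomer | inter_monomer
    overlap: float = 0.0       # max vdW overlap, clash only

    @property
    def pair_key(self) -> Tuple[ResKey, ResKey, str]:
        return (self.res_a, self.res_b, self.kind)


@dataclass
class ContactDiff:
    lost: List[Contact]
    gained: List[Contact]
    site: MutationSpec

    def lost_partners(self) -> set:
        return {c.res_b for c in self.lost}

    def gained_partners(self) -> set:
        return {c.res_b for c in self.gained}


Selection = Union[None, str, Iterable[ResKey]]


def _select(structure: Structure, sel: Selection) -> List[Residue]:
    if sel is None:
        return list(structure.residues())
    if isinstance(sel, str):
        return list(structure.chains[sel])
    keys = set(sel)
    out = [r for r in structure.residues() if r.key in keys]
    missing = keys - {r.key for r in out}
    if missing:
        raise KeyError(f"selection keys not in structure: {sorted(missing)}")
    return out


def _scope(a: ResKey, b: ResKey) -> str:
    return "inter_monomer" if a[0] != b[0] else "intra_monomer"


def _classify_pair(res_a: Residue, res_b: Residue) -> Tuple[float, str]:
    """(min heavy-atom distance, contact kind) for one residue pair."""
    xa = res_a.coords()
    xb = res_b.coords()
    d = np.linalg.norm(xa[:, None, :] - xb[None, :, :], axis=2)
    min_dist = float(d.min())
    # salt bridge?
    kind = "contact"
    for pos, neg in ((res_a, res_b), (res_b, res_a)):
        p_names = POSITIVE_ATOMS.get(pos.aa, ())
        n_names = NEGATIVE_ATOMS.get(neg.aa, ())
        if p_names and n_names:
            pd_ = [a.xyz for a in pos.atoms if a.name in p_names]
            nd_ = [a.xyz for a in neg.atoms if a.name in n_names]
            if pd_ and nd_:
                dd = np.linalg.norm(np.array(pd_)[:, None, :]
                                    - np.array(nd_)[None, :, :], axis=2)
                if dd.min() <= SALT_BRIDGE_CUTOFF:
                    kind = "salt_bridge"
    if kind == "contact":
        ap_a = [a.xyz for a in res_a.atoms if a.name in APOLAR_ATOMS.get(res_a.aa, ())]
        ap_b = [a.xyz for a in res_b.atoms if a.name in APOLAR_ATOMS.get(res_b.aa, ())]
        if ap_a and ap_b:
            dd = np.linalg.norm(np.array(ap_a)[:, None, :]
                                - np.array(ap_b)[None, :, :], axis=2)
            if dd.min() <= HYDROPHOBIC_CUTOFF:
                kind = "hydrophobic"
    return min_dist, kind


def contact_map(structure: Structure, sel_a: Selection = None,
                sel_b: Selection = None,
                cutoff: float = CONTACT_CUTOFF) -> List[Contact]:
    """All residue contacts between two selections.

    A residue pair is reported once (ordered by key) when any heavy-atom
    pair is within *cutoff*; the pair is sub-typed salt_bridge or
    hydrophobic when the tighter criteria are also met.
    """
    ra = _select(structure, sel_a)
    rb = _select(structure, sel_b)
    if not ra or not rb:
        raise ValueError("empty selection")
    # candidate pairs via per-residue centroid tree
    out: List[Contact] = []
    seen = set()
    cb = [r.coords().mean(axis=0) for r in rb]
    tree = cKDTree(np.array(cb))
    max_span = max((np.ptp(r.coords(), axis=0).max() for r in ra + rb),
                   default=0.0)
    search = cutoff + 2 * max_span
    for res_a in ra:
        ca = res_a.coords().mean(axis=0)
        for j in tree.query_ball_point(ca, search):
            res_b = rb[j]
            if res_a.key == res_b.key:
                continue
            key = tuple(sorted((res_a.key, res_b.key)))
            if key in seen:
                continue
            min_dist, kind = _classify_pair(res_a, res_b)
            if min_dist <= cutoff:
                seen.add(key)
                a_key, b_key = key  # canonical orientation: symmetric output
                out.append(Contact(res_a=a_key, res_b=b_key,
                                   min_dist=min_dist, kind=kind,
                                   scope=_scope(a_key, b_key)))
    out.sort(key=lambda c: (c.res_a, c.res_b))
    return out


def detect_clashes(structure: Structure, site: ResKey | Tuple[str, int],
                   radius: float = 8.0,
                   clash_threshold: float = CLASH_THRESHOLD) -> List[Contact]:
    """Steric clashes of one residue against its environment.

    Heavy-atom pairs (site x other residues within *radius*) with vdW
    overlap >= clash_threshold, excluding covalently constrained pairs
    (bonded 1-2/1-3 neighbours and the rigid adjacent-residue peptide
    geometry), aggregated per residue pair with the maximum overlap.
    """
    key = (site[0], site[1], site[2] if len(site) > 2 else "")
    res = structure.residue(*key)
    excl = steric_exclusions(structure, res)
    site_xyz = res.coords()
    coords, vdws, owners = structure.flat_atoms()
    tree = cKDTree(coords)
    per_pair: Dict[ResKey, float] = {}
    per_dist: Dict[ResKey, float] = {}
    for atom in res.atoms:
        for i in tree.query_ball_point(atom.xyz, radius):
            other_res, other_atom = owners[i]
            if other_res.key == res.key:
                continue
            if (atom.name, other_res.key, other_atom.name) in excl:
                continue
            d = float(np.linalg.norm(atom.xyz - other_atom.xyz))
            overlap = atom.vdw + other_atom.vdw - d
            if overlap >= clash_threshold:
                k = other_res.key
                if overlap > per_pair.get(k, -np.inf):
                    per_pair[k] = overlap
                per_dist[k] = min(per_dist.get(k, np.inf), d)
    out = [
        Contact(res_a=res.key, res_b=k, min_dist=per_dist[k], kind="clash",
                scope=_scope(res.key, k), overlap=ov)
        for k, ov in sorted(per_pair.items())
    ]
    return out


def diff_contacts(wt: Structure, mut: Structure, site: ResKey | Tuple[str, int],
                  cutoff: float = CONTACT_CUTOFF,
                  kinds: Optional[Sequence[str]] = None) -> ContactDiff:
    """Lost/gained contacts of the mutated residue, wild type vs mutant.

    The structures must be identical away from *site* (coordinates to
    1e-6 Å).  When *kinds* is given, only those contact kinds enter the
    diff; packing analyses typically diff the hydrophobic and salt-bridge
    sub-types rather than the loose distance contact.
    """
    key = (site[0], site[1], site[2] if len(site) > 2 else "")
    wt_keys = {r.key for r in wt.residues()}
    mut_keys = {r.key for r in mut.residues()}
    if wt_keys != mut_keys:
        raise ValueError("structures have different residue sets")
    for k in wt_keys:
        if k == key:
            continue
        ra, rb = wt.residue(*k), mut.residue(*k)
        if len(ra.atoms) != len(rb.atoms) or not np.allclose(
                ra.coords(), rb.coords(), atol=1e-6):
            raise ValueError(f"structures differ away from the site (at {k})")

    def site_contacts(st: Structure) -> Dict[Tuple[ResKey, str], Contact]:
        contacts = contact_map(st, [key], None, cutoff=cutoff)
        res = {}
        for c in contacts:
            if kinds is not None and c.kind not in kinds:
                continue
            other = c.res_b if c.res_a == key else c.res_a
            res[(other, c.kind)] = Contact(res_a=key, res_b=other,
                                           min_dist=c.min_dist, kind=c.kind,
                                           scope=c.scope, overlap=c.overlap)
        return res

    wt_c = site_contacts(wt)
    mut_c = site_contacts(mut)
    wt_res = wt.residue(*key)
    mut_res = mut.residue(*key)
    lost = [wt_c[k] for k in sorted(set(wt_c) - set(mut_c))]
    gained = [mut_c[k] for k in sorted(set(mut_c) - set(wt_c))]
    spec = MutationSpec(chain=key[0], position=key[1], wt_aa=wt_res.aa,
                        mut_aa=mut_res.aa, icode=key[2])
    return ContactDiff(lost=lost, gained=gained, site=spec)


def salt_bridges(structure: Structure, region: Selection = None) -> List[Contact]:
    """Salt bridges (opposite-charge side-chain N-O pairs <= 4 Å) in *region*."""
    residues = _select(structure, region)
    pos = [r for r in residues if r.aa in POSITIVE_ATOMS]
    neg = [r for r in residues if r.aa in NEGATIVE_ATOMS]
    out = []
    for rp in pos:
        p_xyz = [a.xyz for a in rp.atoms if a.name in POSITIVE_ATOMS[rp.aa]]
        if not p_xyz:
            continue
        for rn in neg:
            n_xyz = [a.xyz for a in rn.atoms if a.name in NEGATIVE_ATOMS[rn.aa]]
            if not n_xyz:
                continue
            d = np.linalg.norm(np.array(p_xyz)[:, None, :]
                               - np.array(n_xyz)[None, :, :], axis=2)
            if d.min() <= SALT_BRIDGE_CUTOFF:
                a_key, b_key = sorted((rp.key, rn.key))
                out.append(Contact(res_a=a_key, res_b=b_key,
                                   min_dist=float(d.min()), kind="salt_bridge",
                                   scope=_scope(rp.key, rn.key)))
    out.sort(key=lambda c: (c.res_a, c.res_b))
    return out


def proline_in_helix(annotation: TopologyAnnotation, spec: MutationSpec) -> bool:
    """True when the mutation introduces a proline inside an annotated helix.

    Prolines restrict the backbone psi range and break mid-helix hydrogen
    bonding; the two N-terminal positions of each helix are exempt (a
    proline is tolerated as a helix starter).
    """
    if spec.mut_aa != "P":
        return False
    for label, (s, e) in annotation.helix_ranges.items():
        if s <= spec.position <= e:
            return spec.position >= s + 2
    return False
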