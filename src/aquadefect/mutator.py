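"""In-silico point mutagenesis by template side-chain replacement.

A mutation replaces one residue's side chain with an idealized template of
the target type (see :mod:`aquadefect.sidechains`), keeping the backbone
fixed.  Chi angles are chosen by exhaustive search over a staggered rotamer
grid (-60/60/180 per chi, plus ±30° perturbations of the best candidate)
against a purely repulsive steric objective, then polished by deterministic
coordinate descent.  No backbone relaxation and no force-field energetics:
the placement is geometric, which is what the downstream clash/contact
analyses measure.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .geometry import dihedral
from .sidechains import SIDECHAIN_ATOMS, build_side_chain, n_chi
from .structure import Atom, Residue, Structure, steric_exclusions, vdw_radius

__all__ = [
    "MutationSpec",
    "PlacementParams",
    "mutate_residue",
    "side_chain_clash_score",
    "measure_chis",
]

PRO_RING_CLOSURE = 1.473   # ideal CD-N bond, Å
PRO_RING_TOL = 0.1


@dataclass(frozen=True)
class MutationSpec:
    chain: str
    position: int
    wt_aa: str
    mut_aa: str
    icode: str = ""

    def __str__(self) -> str:
        return f"{self.wt_aa}{self.position}{self.mut_aa}"


@dataclass
class PlacementParams:
    rotamer_grid: Sequence[float] = (-60.0, 60.0, 180.0)
    perturbations: Sequence[float] = (-30.0, 30.0)
    refine_steps: int = 200
    clash_weight: float = 1.0
    env_radius: float = 8.0
    seed: int = 0


# chi-defining atom quadruples, derived from the template table
def _chi_definitions(aa: str) -> List[Tuple[str, str, str, str]]:
    defs = []
    for name, parent, angle_ref, torsion_ref, _b, _a, tspec in SIDECHAIN_ATOMS.get(aa, []):
        if tspec[0] == "chi" and tspec[2] == 0.0:
            defs.append((torsion_ref, angle_ref, parent, name))
    return defs


def measure_chis(residue: Residue) -> Optional[List[float]]:
    """Measure the chi torsions of *residue* from its coordinates.

    Returns None when any chi-defining atom is absent.
    """
    chis = []
    for quad in _chi_definitions(residue.aa):
        try:
            pts = [residue.atom(n).xyz for n in quad]
        except KeyError:
            return None
        chis.append(dihedral(*pts))
    return chis


def _environment(structure: Structure, site: Residue, center: np.ndarray,
                 radius: float):
    """Heavy atoms of other residues within *radius* of *center*.

    Atoms whose pairing with the site is covalently constrained (see
    :func:`aquadefect.structure.steric_exclusions`) are tagged so the
    scorer can skip those pairs.  Returns (xyz, vdw, excluded_names) where
    excluded_names[i] is the set of site atom names excluded against
    environment atom i (empty for most atoms).
    """
    excl = steric_exclusions(structure, site)
    coords, vdws, owners = structure.flat_atoms()
    tree = cKDTree(coords)
    idx = tree.query_ball_point(center, radius)
    keep_xyz, keep_vdw, keep_excl = [], [], []
    for i in idx:
        res, atom = owners[i]
        if res.key == site.key:
            continue
        names = frozenset(a for (a, rk, b) in excl
                          if rk == res.key and b == atom.name)
        keep_xyz.append(coords[i])
        keep_vdw.append(vdws[i])
        keep_excl.append(names)
    return (np.array(keep_xyz) if keep_xyz else np.zeros((0, 3)),
            np.array(keep_vdw) if keep_vdw else np.zeros(0),
            keep_excl)


def _masked_overlap_score(names, sc_xyz, sc_vdw, env_xyz, env_vdw,
                          env_excl) -> float:
    """Squared-overlap sum with per-pair exclusions by atom name."""
    if len(sc_xyz) == 0 or len(env_xyz) == 0:
        return 0.0
    d = np.linalg.norm(sc_xyz[:, None, :] - env_xyz[None, :, :], axis=2)
    overlap = (sc_vdw[:, None] + env_vdw[None, :]) - d
    np.maximum(overlap, 0.0, out=overlap)
    for j, excluded in enumerate(env_excl):
        if excluded:
            for i, name in enumerate(names):
                if name in excluded:
                    overlap[i, j] = 0.0
    return float(np.sum(overlap * overlap))


def side_chain_clash_score(structure: Structure, site: Tuple[str, int, str] | Tuple[str, int],
                           radius: float = 8.0) -> float:
    """Repulsive overlap score of one residue's side chain vs its environment.

    Sum over heavy-atom pairs (side chain x other residues within *radius*)
    of max(0, vdw_i + vdw_j - d)^2, excluding covalently constrained pairs.
    """
    chain, number = site[0], site[1]
    icode = site[2] if len(site) > 2 else ""
    res = structure.residue(chain, number, icode)
    sc = res.side_chain_atoms()
    if not sc:
        return 0.0
    sc_xyz = np.array([a.xyz for a in sc])
    sc_vdw = np.array([a.vdw for a in sc])
    names = [a.name for a in sc]
    center = sc_xyz.mean(axis=0)
    env_xyz, env_vdw, env_excl = _environment(structure, res, center,
                                              radius + float(sc_vdw.max()) + 2.0)
    return _masked_overlap_score(names, sc_xyz, sc_vdw, env_xyz, env_vdw,
                                 env_excl)


def _score_chis(chis, aa, backbone, env_xyz, env_vdw, env_excl) -> float:
    placed = build_side_chain(backbone["N"], backbone["CA"], backbone["C"], aa, chis)
    xyz = np.array([p[2] for p in placed])
    vdw = np.array([vdw_radius(p[1]) for p in placed])
    names = [p[0] for p in placed]
    return _masked_overlap_score(names, xyz, vdw, env_xyz, env_vdw, env_excl)


def mutate_residue(structure: Structure, spec: MutationSpec,
                   params: Optional[PlacementParams] = None) -> Structure:
    """Return a copy of *structure* with one residue mutated to spec.mut_aa.

    The backbone (and every other residue) is untouched; the new side chain
    is the steric-optimal template placement.  Deterministic: the rotamer
    grid is enumerated in fixed order and refinement is greedy coordinate
    descent with a fixed schedule.
    """
    params = params or PlacementParams()
    out = structure.copy()
    res = out.residue(spec.chain, spec.position, spec.icode)
    if res.aa != spec.wt_aa:
        raise ValueError(
            f"wild-type mismatch at {spec.chain}/{spec.position}: "
            f"found {res.aa}, expected {spec.wt_aa}"
        )
    if res.aa == spec.mut_aa:
        # type-identical replacement is a no-op: the wild-type side chain
        # already satisfies the objective and is kept verbatim
        return out

    # strip the old side chain; keep backbone atoms only
    res.atoms = [a for a in res.atoms if a.is_backbone]
    res.aa = spec.mut_aa
    res.resname = ""
    res.__post_init__()

    for needed in ("N", "CA", "C"):
        if not res.has_atom(needed):
            raise ValueError(f"residue {spec.chain}/{spec.position} lacks backbone atom {needed}")
    backbone = {n: res.atom(n).xyz for n in ("N", "CA", "C")}

    nchi = n_chi(spec.mut_aa)
    env_xyz, env_vdw, env_excl = _environment(
        out, res, backbone["CA"], params.env_radius + 8.0)

    if spec.mut_aa == "G":
        return out

    if nchi == 0:
        best_chis: Tuple[float, ...] = ()
    else:
        candidates: List[Tuple[float, ...]] = list(
            itertools.product(params.rotamer_grid, repeat=nchi))
        best_chis, best_score = None, np.inf
        for cand in candidates:
            s = _score_chis(cand, spec.mut_aa, backbone, env_xyz, env_vdw, env_excl)
            if s < best_score - 1e-12:
                best_score, best_chis = s, cand
        # ±perturbations of the best grid point
        for k in range(nchi):
            for dp in params.perturbations:
                cand = tuple(c + (dp if i == k else 0.0) for i, c in enumerate(best_chis))
                s = _score_chis(cand, spec.mut_aa, backbone, env_xyz, env_vdw, env_excl)
                if s < best_score - 1e-12:
                    best_score, best_chis = s, cand
        # greedy coordinate descent, shrinking step
        chis = list(best_chis)
        step = 15.0
        proposals = 0
        while proposals < params.refine_steps and step > 0.5:
            improved = False
            for k in range(nchi):
                for sgn in (1.0, -1.0):
                    if proposals >= params.refine_steps:
                        break
                    cand = list(chis)
                    cand[k] += sgn * step
                    s = _score_chis(cand, spec.mut_aa, backbone, env_xyz, env_vdw, env_excl)
                    proposals += 1
                    if s < best_score - 1e-12:
                        best_score, chis = s, cand
                        improved = True
            if not improved:
                step *= 0.5
        best_chis = tuple(chis)

    placed = build_side_chain(backbone["N"], backbone["CA"], backbone["C"],
                              spec.mut_aa, best_chis)
    if spec.mut_aa == "P":
        names = {p[0]: p[2] for p in placed}
        closure = float(np.linalg.norm(names["CD"] - backbone["N"]))
        if abs(closure - PRO_RING_CLOSURE) > PRO_RING_TOL:
            raise RuntimeError(
                f"proline ring closure {closure:.3f} Å deviates from "
                f"{PRO_RING_CLOSURE} by more than {PRO_RING_TOL} Å"
            )
    for name, el, xyz in placed:
        res.atoms.append(Atom(name=name, element=el, xyz=xyz,
                              vdw=vdw_radius(el), is_backbone=False))
    return out
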