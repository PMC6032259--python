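"""Idealized side-chain geometry templates.

One canonical internal-coordinate recipe per amino acid: each side-chain
atom is placed by natural-extension (bond length, bond angle, torsion)
from three previously placed atoms.  Rotatable torsions are expressed as
chi angles (chi1 = N-CA-CB-G, chi2 = CA-CB-G-D, ...); ring and terminal
branch torsions are fixed offsets.  Bond lengths/angles follow standard
Engh-Huber-style values to ~0.01 Å / 1°, which is ample for the purely
steric analyses downstream.

The CB torsion (dihedral C-N-CA-CB) is fixed at -122.6°, which yields the
L-configuration: det[N-CA, C-CA, CB-CA] > 0 (checked by tests).
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

import numpy as np

from .geometry import place_atom

__all__ = ["N_CHI", "SIDECHAIN_ATOMS", "build_side_chain", "n_chi", "element_of"]

# torsion spec: ("chi", k, offset_deg) or ("fixed", value_deg)
# atom spec: (name, parent, angle_ref, torsion_ref, bond, angle, torsion_spec)
_Spec = Tuple[str, str, str, str, float, float, tuple]

_CB = ("CB", "CA", "N", "C", 1.530, 110.4, ("fixed", -122.6))

SIDECHAIN_ATOMS: Dict[str, List[_Spec]] = {
    "G": [],
    "A": [_CB],
    "S": [_CB, ("OG", "CB", "CA", "N", 1.417, 110.8, ("chi", 1, 0.0))],
    "C": [_CB, ("SG", "CB", "CA", "N", 1.808, 113.8, ("chi", 1, 0.0))],
    "T": [_CB,
          ("OG1", "CB", "CA", "N", 1.433, 109.6, ("chi", 1, 0.0)),
          ("CG2", "CB", "CA", "N", 1.521, 110.5, ("chi", 1, -120.0))],
    "V": [_CB,
          ("CG1", "CB", "CA", "N", 1.527, 110.5, ("chi", 1, 0.0)),
          ("CG2", "CB", "CA", "N", 1.527, 110.5, ("chi", 1, 122.0))],
    "I": [_CB,
          ("CG1", "CB", "CA", "N", 1.530, 110.4, ("chi", 1, 0.0)),
          ("CG2", "CB", "CA", "N", 1.521, 110.5, ("chi", 1, -122.0)),
          ("CD1", "CG1", "CB", "CA", 1.513, 113.8, ("chi", 2, 0.0))],
    "L": [_CB,
          ("CG", "CB", "CA", "N", 1.530, 116.3, ("chi", 1, 0.0)),
          ("CD1", "CG", "CB", "CA", 1.521, 110.7, ("chi", 2, 0.0)),
          ("CD2", "CG", "CB", "CA", 1.521, 110.7, ("chi", 2, 122.0))],
    "M": [_CB,
          ("CG", "CB", "CA", "N", 1.520, 114.1, ("chi", 1, 0.0)),
          ("SD", "CG", "CB", "CA", 1.803, 112.7, ("chi", 2, 0.0)),
          ("CE", "SD", "CG", "CB", 1.791, 100.9, ("chi", 3, 0.0))],
    "F": [_CB,
          ("CG", "CB", "CA", "N", 1.502, 113.8, ("chi", 1, 0.0)),
          ("CD1", "CG", "CB", "CA", 1.384, 120.8, ("chi", 2, 0.0)),
          ("CD2", "CG", "CB", "CA", 1.384, 120.8, ("chi", 2, 180.0)),
          ("CE1", "CD1", "CG", "CB", 1.382, 120.8, ("fixed", 180.0)),
          ("CE2", "CD2", "CG", "CB", 1.382, 120.8, ("fixed", 180.0)),
          ("CZ", "CE1", "CD1", "CG", 1.378, 120.0, ("fixed", 0.0))],
    "Y": [_CB,
          ("CG", "CB", "CA", "N", 1.502, 113.8, ("chi", 1, 0.0)),
          ("CD1", "CG", "CB", "CA", 1.384, 120.8, ("chi", 2, 0.0)),
          ("CD2", "CG", "CB", "CA", 1.384, 120.8, ("chi", 2, 180.0)),
          ("CE1", "CD1", "CG", "CB", 1.382, 120.8, ("fixed", 180.0)),
          ("CE2", "CD2", "CG", "CB", 1.382, 120.8, ("fixed", 180.0)),
          ("CZ", "CE1", "CD1", "CG", 1.378, 120.0, ("fixed", 0.0)),
          ("OH", "CZ", "CE1", "CD1", 1.376, 119.9, ("fixed", 180.0))],
    "W": [_CB,
          ("CG", "CB", "CA", "N", 1.498, 113.6, ("chi", 1, 0.0)),
          ("CD1", "CG", "CB", "CA", 1.365, 126.9, ("chi", 2, 0.0)),
          ("CD2", "CG", "CB", "CA", 1.433, 126.6, ("chi", 2, 180.0)),
          ("NE1", "CD1", "CG", "CB", 1.374, 110.2, ("fixed", 180.0)),
          ("CE2", "CD2", "CG", "CB", 1.409, 107.2, ("fixed", 180.0)),
          ("CE3", "CD2", "CG", "CB", 1.398, 133.9, ("fixed", 0.0)),
          ("CZ2", "CE2", "CD2", "CG", 1.394, 122.4, ("fixed", 180.0)),
          ("CZ3", "CE3", "CD2", "CG", 1.382, 118.6, ("fixed", 180.0)),
          ("CH2", "CZ2", "CE2", "CD2", 1.368, 117.5, ("fixed", 0.0))],
    "D": [_CB,
          ("CG", "CB", "CA", "N", 1.516, 112.6, ("chi", 1, 0.0)),
          ("OD1", "CG", "CB", "CA", 1.249, 118.4, ("chi", 2, 0.0)),
          ("OD2", "CG", "CB", "CA", 1.249, 118.4, ("chi", 2, 180.0))],
    "N": [_CB,
          ("CG", "CB", "CA", "N", 1.516, 112.7, ("chi", 1, 0.0)),
          ("OD1", "CG", "CB", "CA", 1.231, 120.8, ("chi", 2, 0.0)),
          ("ND2", "CG", "CB", "CA", 1.328, 116.4, ("chi", 2, 180.0))],
    "E": [_CB,
          ("CG", "CB", "CA", "N", 1.520, 114.1, ("chi", 1, 0.0)),
          ("CD", "CG", "CB", "CA", 1.516, 112.6, ("chi", 2, 0.0)),
          ("OE1", "CD", "CG", "CB", 1.249, 118.4, ("chi", 3, 0.0)),
          ("OE2", "CD", "CG", "CB", 1.249, 118.4, ("chi", 3, 180.0))],
    "Q": [_CB,
          ("CG", "CB", "CA", "N", 1.520, 114.1, ("chi", 1, 0.0)),
          ("CD", "CG", "CB", "CA", 1.516, 112.6, ("chi", 2, 0.0)),
          ("OE1", "CD", "CG", "CB", 1.231, 120.8, ("chi", 3, 0.0)),
          ("NE2", "CD", "CG", "CB", 1.328, 116.4, ("chi", 3, 180.0))],
    "K": [_CB,
          ("CG", "CB", "CA", "N", 1.520, 114.1, ("chi", 1, 0.0)),
          ("CD", "CG", "CB", "CA", 1.520, 111.3, ("chi", 2, 0.0)),
          ("CE", "CD", "CG", "CB", 1.520, 111.3, ("chi", 3, 0.0)),
          ("NZ", "CE", "CD", "CG", 1.489, 111.9, ("chi", 4, 0.0))],
    "R": [_CB,
          ("CG", "CB", "CA", "N", 1.520, 114.1, ("chi", 1, 0.0)),
          ("CD", "CG", "CB", "CA", 1.520, 111.3, ("chi", 2, 0.0)),
          ("NE", "CD", "CG", "CB", 1.461, 112.0, ("chi", 3, 0.0)),
          ("CZ", "NE", "CD", "CG", 1.329, 124.2, ("chi", 4, 0.0)),
          ("NH1", "CZ", "NE", "CD", 1.326, 120.0, ("fixed", 0.0)),
          ("NH2", "CZ", "NE", "CD", 1.326, 120.0, ("fixed", 180.0))],
    "H": [_CB,
          ("CG", "CB", "CA", "N", 1.492, 113.8, ("chi", 1, 0.0)),
          ("ND1", "CG", "CB", "CA", 1.380, 122.7, ("chi", 2, 0.0)),
          ("CD2", "CG", "CB", "CA", 1.354, 131.0, ("chi", 2, 180.0)),
          ("CE1", "ND1", "CG", "CB", 1.326, 109.3, ("fixed", 180.0)),
          ("NE2", "CD2", "CG", "CB", 1.373, 107.2, ("fixed", 180.0))],
    # Proline ring: torsions fixed at a canonical down pucker; closure
    # CD-N is verified against 1.473 Å by the mutator (0.1 Å tolerance).
    "P": [("CB", "CA", "N", "C", 1.530, 103.2, ("fixed", -120.0)),
          ("CG", "CB", "CA", "N", 1.495, 104.5, ("fixed", -28.0)),
          ("CD", "CG", "CB", "CA", 1.507, 105.5, ("fixed", 40.0))],
}

N_CHI: Dict[str, int] = {
    "G": 0, "A": 0, "P": 0,
    "S": 1, "C": 1, "T": 1, "V": 1,
    "I": 2, "L": 2, "F": 2, "Y": 2, "W": 2, "D": 2, "N": 2, "H": 2,
    "M": 3, "E": 3, "Q": 3,
    "K": 4, "R": 4,
}


def n_chi(aa: str) -> int:
    if aa not in N_CHI:
        raise KeyError(f"unknown amino acid code {aa!r}")
    return N_CHI[aa]


def element_of(atom_name: str) -> str:
    """Element symbol from a standard side-chain atom name."""
    c = atom_name[0]
    if c in ("N", "O", "S", "C"):
        return c
    raise ValueError(f"cannot infer element for atom {atom_name!r}")


def build_side_chain(n_xyz, ca_xyz, c_xyz, aa: str,
                     chis: Sequence[float] = ()) -> List[Tuple[str, str, np.ndarray]]:
    """Build ideal side-chain coordinates for residue type *aa*.

    Parameters are the backbone N/CA/C positions and the chi torsions
    (missing chis default to 180°, the extended conformer).  Returns a list
    of (atom_name, element, xyz); empty for glycine.
    """
    if aa not in SIDECHAIN_ATOMS:
        raise KeyError(f"unknown amino acid code {aa!r}")
    placed = {"N": np.asarray(n_xyz, float),
              "CA": np.asarray(ca_xyz, float),
              "C": np.asarray(c_xyz, float)}
    chis = list(chis)
    out: List[Tuple[str, str, np.ndarray]] = []
    for name, parent, angle_ref, torsion_ref, bond, angle, tspec in SIDECHAIN_ATOMS[aa]:
        if tspec[0] == "fixed":
            torsion = tspec[1]
        else:
            _, k, offset = tspec
            chi = chis[k - 1] if k - 1 < len(chis) else 180.0
            torsion = chi + offset
        xyz = place_atom(placed[torsion_ref], placed[angle_ref], placed[parent],
                         bond, angle, torsion)
        placed[name] = xyz
        out.append((name, element_of(name), xyz))
    return out
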