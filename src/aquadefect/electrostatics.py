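"""Finite-difference linearized Poisson-Boltzmann electrostatics.

Potentials are in kT/e at the configured temperature; lengths in Å.  The
dielectric map is two-valued: eps_solute inside the van-der-Waals spheres,
eps_solvent outside (no reentrant surface), with the Debye term active in
solvent only.  Charges are formal: +1 on Arg CZ and Lys NZ, -1 at the
carboxylate-oxygen midpoint of Asp/Glu; His neutral.  The solver is
successive over-relaxation on a 7-point stencil with two-pass focusing
(coarse grid over the padded box, fine grid refined with boundary values
interpolated from the coarse solution).

These choices reproduce sign and locality of surface-potential changes on
mutation; absolute magnitudes would need force-field partial charges and a
molecular surface, which are out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .structure import Structure

__all__ = [
    "PBParams",
    "PotentialGrid",
    "assign_charges",
    "solve_pb",
    "surface_potential_delta",
    "COULOMB_KT",
]

# e^2 / (4 pi eps0) in kT*Å at 298 K
COULOMB_KT = 561.0


@dataclass
class PBParams:
    eps_solute: float = 1.0
    eps_solvent: float = 80.0
    grid_spacing_coarse: float = 1.5
    grid_spacing_fine: float = 1.0
    ionic_strength: float = 0.0      # mol/L
    temperature: float = 298.0
    padding: float = 12.0
    sor_omega: float = 1.8
    tolerance: float = 1e-4          # max |update| per sweep, kT/e
    max_iterations: int = 20000

    def __post_init__(self) -> None:
        if self.grid_spacing_coarse <= 0 or self.grid_spacing_fine <= 0:
            raise ValueError("grid spacings must be positive")
        if self.grid_spacing_fine > self.grid_spacing_coarse:
            raise ValueError("fine spacing must not exceed coarse spacing")
        if self.eps_solute < 1 or self.eps_solvent < 1:
            raise ValueError("dielectric constants must be >= 1")

    @property
    def kappa2_eps(self) -> float:
        """kappa^2 * eps_solvent in Å^-2 from the ionic strength."""
        number_density = self.ionic_strength * 6.022e-4   # particles / Å^3
        return 8.0 * np.pi * COULOMB_KT * number_density


@dataclass
class PotentialGrid:
    origin: np.ndarray
    spacing: float
    dims: Tuple[int, int, int]
    values: np.ndarray           # kT/e, shape dims
    eps_map: np.ndarray
    kappa_map: np.ndarray

    def axes(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(self.origin[i] + self.spacing * np.arange(self.dims[i])
                     for i in range(3))

    def potential_at(self, points: np.ndarray) -> np.ndarray:
        interp = RegularGridInterpolator(self.axes(), self.values,
                                         bounds_error=False, fill_value=0.0)
        return interp(np.atleast_2d(points))

    def node_coords(self) -> np.ndarray:
        ax = self.axes()
        gx, gy, gz = np.meshgrid(*ax, indexing="ij")
        return np.stack([gx, gy, gz], axis=-1)

    def export_dx(self, path) -> None:
        """Write the potential as an OpenDX scalar field."""
        nx, ny, nz = self.dims
        with open(path, "w") as fh:
            fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
            fh.write("origin {:.6f} {:.6f} {:.6f}\n".format(*self.origin))
            fh.write(f"delta {self.spacing:.6f} 0 0\n")
            fh.write(f"delta 0 {self.spacing:.6f} 0\n")
            fh.write(f"delta 0 0 {self.spacing:.6f}\n")
            fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
            fh.write(f"object 3 class array type double rank 0 items "
                     f"{nx * ny * nz} data follows\n")
            flat = self.values.ravel(order="C")
            for i in range(0, len(flat), 3):
                fh.write(" ".join(f"{v:.6e}" for v in flat[i:i + 3]) + "\n")
            fh.write('attribute "dep" string "positions"\n')
            fh.write('object "regular positions regular connections" class field\n')


def assign_charges(structure: Structure,
                   include_termini: bool = False) -> List[Tuple[np.ndarray, float]]:
    """Formal side-chain charges: (position, charge in e) list.

    Arg -> +1 at CZ, Lys -> +1 at NZ, Asp/Glu -> -1 at the midpoint of the
    carboxylate oxygens; His neutral.  Residues missing their charged-group
    atoms are skipped with a warning.
    """
    out: List[Tuple[np.ndarray, float]] = []
    for res in structure.residues():
        try:
            if res.aa == "R":
                out.append((res.atom("CZ").xyz.copy(), +1.0))
            elif res.aa == "K":
                out.append((res.atom("NZ").xyz.copy(), +1.0))
            elif res.aa == "D":
                mid = 0.5 * (res.atom("OD1").xyz + res.atom("OD2").xyz)
                out.append((mid, -1.0))
            elif res.aa == "E":
                mid = 0.5 * (res.atom("OE1").xyz + res.atom("OE2").xyz)
                out.append((mid, -1.0))
        except KeyError:
            warnings.warn(f"residue {res.resname}{res.number} lacks charged-group "
                          "atoms; skipped")
    if include_termini:
        for cid, residues in structure.chains.items():
            first, last = residues[0], residues[-1]
            if first.has_atom("N"):
                out.append((first.atom("N").xyz.copy(), +1.0))
            if last.has_atom("OXT"):
                out.append((last.atom("OXT").xyz.copy(), -1.0))
            elif last.has_atom("O"):
                out.append((last.atom("O").xyz.copy(), -1.0))
    return out


def _build_maps(structure: Optional[Structure], axes, params: PBParams):
    nx, ny, nz = (len(a) for a in axes)
    eps = np.full((nx, ny, nz), params.eps_solvent)
    if structure is not None:
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        coords, vdw, _ = structure.flat_atoms()
        for xyz, r in zip(coords, vdw):
            inside = ((gx - xyz[0]) ** 2 + (gy - xyz[1]) ** 2
                      + (gz - xyz[2]) ** 2) <= r * r
            eps[inside] = params.eps_solute
    kappa2eps = np.where(eps == params.eps_solvent, params.kappa2_eps, 0.0)
    return eps, kappa2eps


def _spread_charges(charges, axes, spacing) -> np.ndarray:
    """Trilinear charge assignment to grid nodes (units: e per node)."""
    nx, ny, nz = (len(a) for a in axes)
    q = np.zeros((nx, ny, nz))
    o = np.array([axes[0][0], axes[1][0], axes[2][0]])
    for xyz, charge in charges:
        t = (np.asarray(xyz) - o) / spacing
        i0 = np.floor(t).astype(int)
        f = t - i0
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    w = ((f[0] if dx else 1 - f[0])
                         * (f[1] if dy else 1 - f[1])
                         * (f[2] if dz else 1 - f[2]))
                    ix, iy, iz = i0[0] + dx, i0[1] + dy, i0[2] + dz
                    if 0 <= ix < nx and 0 <= iy < ny and 0 <= iz < nz:
                        q[ix, iy, iz] += charge * w
    return q


def _boundary_potential(charges, axes, params: PBParams) -> np.ndarray:
    """Debye-Hückel potential of the charge set, evaluated on all nodes."""
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    phi = np.zeros_like(gx)
    kappa = np.sqrt(params.kappa2_eps / params.eps_solvent) \
        if params.kappa2_eps > 0 else 0.0
    for xyz, q in charges:
        r = np.sqrt((gx - xyz[0]) ** 2 + (gy - xyz[1]) ** 2 + (gz - xyz[2]) ** 2)
        r = np.maximum(r, 1e-6)
        phi += COULOMB_KT * q * np.exp(-kappa * r) / (params.eps_solvent * r)
    return phi


def _sor(eps, kappa2eps, q, phi, spacing, params: PBParams) -> np.ndarray:
    """Red-black SOR for div(eps grad phi) - kappa^2 eps_w phi = -4 pi C rho."""
    h = spacing
    src = 4.0 * np.pi * COULOMB_KT * q / h   # (4 pi C q / h^3) * h^2
    nx, ny, nz = eps.shape
    # link dielectrics (mean of adjacent nodes)
    exm = np.zeros_like(eps); exp_ = np.zeros_like(eps)
    eym = np.zeros_like(eps); eyp = np.zeros_like(eps)
    ezm = np.zeros_like(eps); ezp = np.zeros_like(eps)
    exm[1:, :, :] = 0.5 * (eps[1:, :, :] + eps[:-1, :, :])
    exp_[:-1, :, :] = 0.5 * (eps[:-1, :, :] + eps[1:, :, :])
    eym[:, 1:, :] = 0.5 * (eps[:, 1:, :] + eps[:, :-1, :])
    eyp[:, :-1, :] = 0.5 * (eps[:, :-1, :] + eps[:, 1:, :])
    ezm[:, :, 1:] = 0.5 * (eps[:, :, 1:] + eps[:, :, :-1])
    ezp[:, :, :-1] = 0.5 * (eps[:, :, :-1] + eps[:, :, 1:])
    diag = exm + exp_ + eym + eyp + ezm + ezp + kappa2eps * h * h

    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    interior = ((ii > 0) & (ii < nx - 1) & (jj > 0) & (jj < ny - 1)
                & (kk > 0) & (kk < nz - 1))
    colors = [(interior & (((ii + jj + kk) % 2) == c)) for c in (0, 1)]
    omega = params.sor_omega
    for it in range(params.max_iterations):
        max_update = 0.0
        for mask in colors:
            neigh = np.zeros_like(phi)
            neigh[1:-1, 1:-1, 1:-1] = (
                exm[1:-1, 1:-1, 1:-1] * phi[:-2, 1:-1, 1:-1]
                + exp_[1:-1, 1:-1, 1:-1] * phi[2:, 1:-1, 1:-1]
                + eym[1:-1, 1:-1, 1:-1] * phi[1:-1, :-2, 1:-1]
                + eyp[1:-1, 1:-1, 1:-1] * phi[1:-1, 2:, 1:-1]
                + ezm[1:-1, 1:-1, 1:-1] * phi[1:-1, 1:-1, :-2]
                + ezp[1:-1, 1:-1, 1:-1] * phi[1:-1, 1:-1, 2:]
            )
            new = (neigh + src) / diag
            delta = omega * (new - phi)
            phi = np.where(mask, phi + delta, phi)
            max_update = max(max_update, float(np.abs(delta[mask]).max()))
        if max_update < params.tolerance:
            return phi
    raise RuntimeError(
        f"PB solver did not converge: residual {max_update:.2e} kT/e after "
        f"{params.max_iterations} iterations"
    )


def _solve_on_grid(structure, charges, axes, spacing, params,
                   boundary: Optional[np.ndarray] = None) -> PotentialGrid:
    eps, kappa2eps = _build_maps(structure, axes, params)
    q = _spread_charges(charges, axes, spacing)
    if boundary is None:
        phi = _boundary_potential(charges, axes, params)
    else:
        phi = boundary
    if any(abs(float(c[1])) > 0 for c in charges) or structure is not None:
        phi = _sor(eps, kappa2eps, q, phi, spacing, params)
    origin = np.array([axes[0][0], axes[1][0], axes[2][0]])
    return PotentialGrid(origin=origin, spacing=spacing,
                         dims=tuple(len(a) for a in axes), values=phi,
                         eps_map=eps, kappa_map=kappa2eps)


def _make_axes(lo, hi, spacing, min_dims=8):
    axes = []
    for d in range(3):
        n = max(int(np.ceil((hi[d] - lo[d]) / spacing)) + 1, min_dims)
        axes.append(lo[d] + spacing * np.arange(n))
    return tuple(axes)


def solve_pb(structure: Optional[Structure],
             charges: Sequence[Tuple[np.ndarray, float]],
             params: Optional[PBParams] = None) -> PotentialGrid:
    """Solve the linearized PB equation with coarse-to-fine focusing.

    *structure* provides the dielectric boundary (None gives a uniform
    solvent dielectric, the analytic Coulomb limit).  Returns the fine
    grid; potentials in kT/e.
    """
    params = params or PBParams()
    if charges is None:
        charges = []
    if structure is not None:
        coords, vdw, _ = structure.flat_atoms()
        lo = coords.min(axis=0)
        hi = coords.max(axis=0)
    elif charges:
        pts = np.array([c[0] for c in charges])
        lo, hi = pts.min(axis=0), pts.max(axis=0)
    else:
        lo = hi = np.zeros(3)

    coarse_axes = _make_axes(lo - params.padding, hi + params.padding,
                             params.grid_spacing_coarse)
    coarse = _solve_on_grid(structure, charges, coarse_axes,
                            params.grid_spacing_coarse, params)
    if not charges:
        # zero-charge shortcut still goes through a coarse solve; fine grid
        # is identically zero
        pass
    fine_pad = max(params.padding / 2.0, 4.0)
    fine_axes = _make_axes(lo - fine_pad, hi + fine_pad,
                           params.grid_spacing_fine)
    interp = RegularGridInterpolator(coarse.axes(), coarse.values,
                                     bounds_error=False, fill_value=0.0)
    gx, gy, gz = np.meshgrid(*fine_axes, indexing="ij")
    boundary = interp(np.stack([gx, gy, gz], axis=-1))
    fine = _solve_on_grid(structure, charges, fine_axes,
                          params.grid_spacing_fine, params, boundary=boundary)
    return fine


def surface_potential_delta(wt_grid: PotentialGrid, mut_grid: PotentialGrid,
                            site_xyz: np.ndarray, radius: float = 8.0) -> dict:
    """Mean/extreme potential change over solvent nodes near the site.

    Grids must share origin, spacing and dims; solvent nodes are those
    marked solvent in both dielectric maps.
    """
    if (wt_grid.dims != mut_grid.dims
            or abs(wt_grid.spacing - mut_grid.spacing) > 1e-9
            or not np.allclose(wt_grid.origin, mut_grid.origin)):
        raise ValueError("potential grids are on different lattices")
    eps_w = wt_grid.eps_map.max()
    solvent = (wt_grid.eps_map == eps_w) & (mut_grid.eps_map == eps_w)
    coords = wt_grid.node_coords()
    near = np.linalg.norm(coords - np.asarray(site_xyz), axis=-1) <= radius
    mask = solvent & near
    if not mask.any():
        raise ValueError("no solvent nodes within radius of the site")
    delta = mut_grid.values[mask] - wt_grid.values[mask]
    return {
        "mean": float(delta.mean()),
        "min": float(delta.min()),
        "max": float(delta.max()),
        "n_nodes": int(mask.sum()),
    }
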