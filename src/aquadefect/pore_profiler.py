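"""Pore-radius profiling by maximal-sphere search along a channel axis.

For each slice plane perpendicular to the channel axis, the largest sphere
that fits among the van-der-Waals spheres of the protein, with its centre
constrained to the plane, is found by seeded simulated annealing (step
0.5 Å decaying ×0.9 every 50 proposals) followed by a derivative-free
polish.  The radius of that sphere as a function of the axial coordinate is
the pore profile; slices whose radius reaches r_max are flagged open
(end of the pore).

Wild-type and mutant profiles are compared on a common z grid; sustained
radius reductions are reported as narrowing regions labelled cytoplasmic
(z < z0) or extracellular (z > z0) relative to the pore centre z0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy.optimize import minimize

from .geometry import unit
from .structure import Structure, TopologyAnnotation

__all__ = [
    "PoreAxis",
    "PoreProfile",
    "ProfileDelta",
    "ProfilerParams",
    "estimate_axis",
    "max_sphere_in_slice",
    "compute_profile",
    "compare_profiles",
]


@dataclass
class PoreAxis:
    """Channel axis: origin, unit direction (+ = extracellular), z extent."""

    origin: np.ndarray
    direction: np.ndarray
    z_min: float
    z_max: float

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, float)
        self.direction = unit(np.asarray(self.direction, float))
        if self.z_min >= self.z_max:
            raise ValueError("z_min must be below z_max")
        # orthonormal in-plane basis
        ref = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(ref, self.direction)) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        self.e1 = unit(np.cross(self.direction, ref))
        self.e2 = np.cross(self.direction, self.e1)

    def to_frame(self, xyz: np.ndarray) -> np.ndarray:
        """Lab coordinates -> (u, v, z) in the axis frame."""
        rel = np.atleast_2d(xyz) - self.origin
        out = np.column_stack([rel @ self.e1, rel @ self.e2, rel @ self.direction])
        return out if np.ndim(xyz) > 1 else out[0]

    def from_frame(self, uvz: np.ndarray) -> np.ndarray:
        u, v, z = uvz
        return self.origin + u * self.e1 + v * self.e2 + z * self.direction


@dataclass
class ProfilerParams:
    step: float = 0.5          # slice spacing, Å
    r_max: float = 10.0        # open-channel cap, Å
    seed: int = 0
    anneal_steps: int = 400
    sa_step0: float = 0.5      # initial SA step, Å
    sa_decay: float = 0.9      # decay applied every 50 proposals
    sa_temp0: float = 0.1      # initial Metropolis temperature, Å of clearance


@dataclass
class PoreProfile:
    z: np.ndarray              # axial coordinate of each slice
    radius: np.ndarray
    open_flag: np.ndarray      # True where radius hit the r_max cap
    centers: np.ndarray        # sphere centres, lab frame, [n, 3]
    axis: PoreAxis
    z0: float                  # pore-centre reference
    step: float

    def interior(self) -> np.ndarray:
        """Mask of non-open slices."""
        return ~self.open_flag

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("z\tradius\topen\n")
            for z, r, o in zip(self.z, self.radius, self.open_flag):
                fh.write(f"{z:.3f}\t{r:.4f}\t{int(o)}\n")


@dataclass
class NarrowingRegion:
    z_start: float
    z_end: float
    max_reduction: float
    side: str                  # cytoplasmic | extracellular | spanning


@dataclass
class ProfileDelta:
    z: np.ndarray
    delta: np.ndarray          # wt radius - mutant radius, Å
    narrowing_regions: List[NarrowingRegion]
    threshold: float
    min_run: int

    @property
    def max_narrowing(self) -> float:
        return float(max((r.max_reduction for r in self.narrowing_regions),
                         default=0.0))


def estimate_axis(structure: Structure,
                  annotation: Optional[TopologyAnnotation] = None,
                  flip: bool = False) -> PoreAxis:
    """Principal inertial axis of the (transmembrane) CA atoms.

    Channels analysed here are near-axial helix bundles, so the direction
    of largest coordinate variance of the CA set is the channel direction.
    Falls back to all atoms for pseudo-atom structures without CA.  Raises
    for near-spherical atom clouds, where no axis is defined.
    """
    if structure.n_atoms() < 50:
        raise ValueError("need at least 50 atoms to estimate a channel axis")
    pts = []
    for r in structure.residues():
        if annotation is not None:
            lab = annotation.label_of(r.number)
            if not (lab.startswith("H") or lab in ("HB", "HE")):
                continue
        if r.has_atom("CA"):
            pts.append(r.atom("CA").xyz)
    if len(pts) < 10:
        pts = [a.xyz for res in structure.residues() for a in res.atoms]
    pts = np.asarray(pts, float)
    centroid = pts.mean(axis=0)
    _, s, vt = np.linalg.svd(pts - centroid, full_matrices=False)
    if s[0] < 1.2 * s[1]:
        raise ValueError("degenerate inertia tensor: supply the axis explicitly")
    direction = vt[0]
    if direction[2] < 0:
        direction = -direction
    if flip:
        direction = -direction
    proj = (pts - centroid) @ direction
    return PoreAxis(origin=centroid, direction=direction,
                    z_min=float(proj.min()) - 5.0, z_max=float(proj.max()) + 5.0)


def _clearance(uv: np.ndarray, frame_xyz: np.ndarray, vdw: np.ndarray,
               z: float) -> float:
    """Distance from slice point (u, v, z) to the nearest atom surface."""
    d = np.sqrt((frame_xyz[:, 0] - uv[0]) ** 2
                + (frame_xyz[:, 1] - uv[1]) ** 2
                + (frame_xyz[:, 2] - z) ** 2) - vdw
    return float(d.min())


def max_sphere_in_slice(coords: np.ndarray, vdw: np.ndarray, axis: PoreAxis,
                        z: float, params: Optional[ProfilerParams] = None,
                        start_center: Optional[np.ndarray] = None
                        ) -> Tuple[np.ndarray, float, bool]:
    """Largest sphere centred in the slice plane at axial coordinate *z*.

    Returns (centre in lab frame, radius, open_flag).  The radius is capped
    at params.r_max; slices with no atoms in reach are open by definition.
    """
    params = params or ProfilerParams()
    if params.r_max <= 0:
        raise ValueError("r_max must be positive")
    frame = axis.to_frame(coords)
    reach = params.r_max + (float(vdw.max()) if len(vdw) else 0.0)
    mask = np.abs(frame[:, 2] - z) <= reach
    if start_center is None:
        uv = np.zeros(2)
    else:
        sc = axis.to_frame(np.asarray(start_center, float))
        uv = np.array([sc[0], sc[1]])
    if not np.any(mask):
        return axis.from_frame(np.array([uv[0], uv[1], z])), params.r_max, True
    fx, fv = frame[mask], vdw[mask]

    rng = np.random.default_rng(params.seed + int(round(z * 1000)) % (2 ** 20))
    cur_uv = uv.copy()
    cur_r = _clearance(cur_uv, fx, fv, z)
    best_uv, best_r = cur_uv.copy(), cur_r
    step = params.sa_step0
    temperature = params.sa_temp0
    for i in range(params.anneal_steps):
        if i > 0 and i % 50 == 0:
            step *= params.sa_decay
            temperature *= params.sa_decay
        cand = cur_uv + step * rng.standard_normal(2)
        r = _clearance(cand, fx, fv, z)
        delta = r - cur_r
        # downhill moves are Metropolis-accepted only between atoms (r > 0):
        # a centre inside the vdW wall is never a valid sphere position, and
        # accepting one would let the walker tunnel out of the lumen
        if delta > 0 or (r > 0 and
                         rng.random() < np.exp(delta / max(temperature, 1e-9))):
            cur_uv, cur_r = cand, r
        if cur_r > best_r:
            best_uv, best_r = cur_uv.copy(), cur_r
        if best_r >= params.r_max:
            break
    if best_r < params.r_max:
        res = minimize(lambda p: -_clearance(p, fx, fv, z), best_uv,
                       method="Nelder-Mead",
                       options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 400})
        if -res.fun > best_r:
            best_r, best_uv = -float(res.fun), res.x
    open_flag = best_r >= params.r_max
    radius = min(best_r, params.r_max)
    center = axis.from_frame(np.array([best_uv[0], best_uv[1], z]))
    return center, radius, open_flag


def compute_profile(structure: Structure, axis: PoreAxis,
                    params: Optional[ProfilerParams] = None,
                    annotation: Optional[TopologyAnnotation] = None
                    ) -> PoreProfile:
    """Profile the pore radius every params.step Å from z_min to z_max.

    Each slice search is seeded from the previous slice's centre (the first
    from the axis origin), letting the sphere track a curving lumen.  The
    pore-centre reference z0 is the radius minimum within the NPA region
    when an annotation provides one, else the global interior minimum.
    """
    params = params or ProfilerParams()
    coords, vdw, _ = structure.flat_atoms()
    zs = np.arange(axis.z_min, axis.z_max + 1e-9, params.step)
    centers, radii, flags = [], [], []
    prev_center = axis.origin
    for z in zs:
        c, r, o = max_sphere_in_slice(coords, vdw, axis, float(z), params,
                                      start_center=prev_center)
        centers.append(c)
        radii.append(r)
        flags.append(o)
        if not o:
            prev_center = c
    radii = np.array(radii)
    flags = np.array(flags, dtype=bool)
    if flags.all():
        raise ValueError("no channel found: every slice is open")
    interior = ~flags
    z0 = None
    if annotation is not None and annotation.npa_residues:
        npa_z = []
        for r in structure.residues():
            if r.number in annotation.npa_residues:
                for a in r.atoms:
                    npa_z.append(axis.to_frame(a.xyz)[2])
        if npa_z:
            lo, hi = min(npa_z) - 2.0, max(npa_z) + 2.0
            band = interior & (zs >= lo) & (zs <= hi)
            if band.any():
                masked = np.where(band, radii, np.inf)
                z0 = float(zs[int(np.argmin(masked))])
    if z0 is None:
        masked = np.where(interior, radii, np.inf)
        z0 = float(zs[int(np.argmin(masked))])
    return PoreProfile(z=zs, radius=radii, open_flag=flags,
                       centers=np.array(centers), axis=axis, z0=z0,
                       step=params.step)


def compare_profiles(wt: PoreProfile, mut: PoreProfile,
                     threshold: float = 0.3, min_run: int = 3) -> ProfileDelta:
    """Per-z radius difference (wt - mutant) and sustained narrowing regions.

    Profiles on different z grids are linearly resampled onto the wild-type
    grid over the overlapping range; disjoint ranges are an error.  A
    narrowing region is >= min_run consecutive slices with reduction >=
    threshold; its side is judged against the wild-type pore centre z0.
    """
    lo = max(wt.z[0], mut.z[0])
    hi = min(wt.z[-1], mut.z[-1])
    if lo >= hi:
        raise ValueError("profiles cover disjoint z ranges")
    sel = (wt.z >= lo) & (wt.z <= hi)
    z = wt.z[sel]
    wt_r = wt.radius[sel]
    mut_r = np.interp(z, mut.z, mut.radius)
    valid = wt.interior()[sel]
    delta = np.where(valid, wt_r - mut_r, 0.0)

    regions: List[NarrowingRegion] = []
    above = delta >= threshold
    i = 0
    n = len(z)
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            if j - i + 1 >= min_run:
                seg = delta[i:j + 1]
                mid = 0.5 * (z[i] + z[j])
                if z[j] < wt.z0:
                    side = "cytoplasmic"
                elif z[i] > wt.z0:
                    side = "extracellular"
                else:
                    side = "cytoplasmic" if mid < wt.z0 else "extracellular"
                regions.append(NarrowingRegion(float(z[i]), float(z[j]),
                                               float(seg.max()), side))
            i = j + 1
        else:
            i += 1
    return ProfileDelta(z=z, delta=delta, narrowing_regions=regions,
                        threshold=threshold, min_run=min_run)
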