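# Methods

This note documents the models, numerical choices and limitations behind
each stage of the pipeline. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Coordinate model

Structures are chains of residues of heavy atoms; hydrogens are discarded
at load time. Crystallographic channel structures rarely resolve
hydrogens, so every steric criterion downstream is defined on heavy atoms
with Bondi van-der-Waals radii (C 1.70, N 1.55, O 1.52, S 1.80 Å; unknown
elements fall back to 1.70 Å with a warning). Alternate locations keep the
highest-occupancy conformer. Coordinates are right-handed Å; the channel
axis is stored explicitly with its positive direction pointing
extracellular (a flag flips it), so profiles read cytoplasmic→extracellular.

C4 assemblies are built by successive 90° rotations of a single-chain
monomer about a given axis; being pure rotations they preserve
intra-monomer distances exactly, which a test asserts.

Steric scoring excludes atom pairs whose separation is fixed by covalent
geometry rather than packing: bonded 1-2/1-3 pairs, the 1-4 pairs
involving CB and the proline CD–N attachment, and *all* backbone–backbone
pairs of sequence-adjacent residues. The last rule is broader than a
bond-count cutoff because the trans-peptide unit holds, for example, the
carbonyl O(i)···C(i+1) pair ~0.3 Å below vdW contact in α-helices (the
n→π* approach); these separations are invariant under point mutation and
would otherwise register as clashes on every residue of every helix.

## Side-chain templates and mutation

Each amino acid has one idealized internal-coordinate recipe: bond
lengths/angles at standard values (~0.01 Å / 1°), side-chain atoms placed
by natural-extension frames, rotatable torsions exposed as chi angles and
ring/branch torsions fixed. The CB improper (dihedral C–N–CA–CB) is
−122.6°, which yields the L-configuration (det[N−CA, C−CA, CB−CA] > 0;
verified in tests against the chirality of reference residue templates).
Proline is built with a fixed canonical pucker and its CD–N closure is
checked against 1.473 Å with a 0.1 Å tolerance.

A mutation strips the old side chain (backbone untouched, no other atom
moves), then searches chi space: the staggered grid (−60°, 60°, 180° per
chi), ±30° perturbations of the best grid point, then greedy coordinate
descent with a halving step (≤200 proposals, stop at 0.5°). The objective
is purely repulsive: the sum of squared vdW overlaps against the
environment within 8 Å. Consequences of this design:

* placement is deterministic (fixed enumeration order, greedy descent), so
  a fixed seed trivially reproduces coordinates bit-for-bit;
* the refined score never exceeds the best raw rotamer (tested);
* mutating a residue to its own type is a no-op — the existing side chain
  already satisfies the objective and is kept verbatim;
* there is no backbone relaxation, no attractive term and no force-field
  energetics. The mutant is the *least-strained rigid-backbone placement*;
  the residual overlap score is the evidence of interest, not a
  minimized-energy structure. Conclusions are therefore at the level of
  clash/contact patterns, not atomic accuracy.

## Pore profiling

The profile is the HOLE-style maximal-sphere radius along the axis:
`r(z) = max_c min_i (|c − x_i| − vdw_i)` with the centre `c` constrained
to the slice plane at height z (no 3D wander — a simplification adequate
for near-axial channels, and a documented deviation from the original
3D search). The maximization is simulated annealing — Gaussian steps of
initial size 0.5 Å decaying ×0.9 every 50 proposals, 400 proposals,
Metropolis acceptance with initial temperature 0.1 Å of clearance —
followed by a Nelder–Mead polish. Two guards matter:

* downhill moves are only accepted between atoms (clearance > 0): a centre
  inside the wall is never a valid sphere position, and accepting one
  would let the walker tunnel through a thin wall to the unbounded
  outside, where clearance grows without limit;
* the temperature is much smaller than the step so the walker can hop
  between local maxima separated by shallow saddles (irregular lumina)
  but cannot climb out through a wall gap.

Each slice is seeded from the previous slice's centre (the first from the
axis origin), letting the sphere track a curving lumen. Radii cap at
`r_max` = 10 Å, beyond which the slice is declared open — the end-of-pore
behaviour; a profile that is open everywhere is an error ("no channel
found"). The slice step defaults to 0.5 Å. Accuracy, measured against
walls of prescribed radius and an exhaustive 0.01 Å grid search, is a few
hundredths of an Å (asserted at 0.15 Å / 0.05 Å in the acceptance
properties). The per-slice RNG stream is derived from the seed and the
slice height, so a fixed seed gives byte-identical profiles.

The axis is estimated as the direction of largest coordinate variance of
the (transmembrane, when annotated) CA atoms — appropriate for helix
bundles, whose long axis is the channel direction; near-spherical atom
clouds are rejected as degenerate and require a user-supplied axis. The
pore-centre reference z0 is the radius minimum within the NPA region when
a topology annotation provides one (the physical mid-channel
constriction), else the global interior minimum.

Profile comparison resamples the mutant onto the wild-type z grid
(linear interpolation), and reports *narrowing regions*: runs of at least
`min_run` = 3 consecutive slices with radius reduction ≥ 0.3 Å, labelled
cytoplasmic (z < z0) or extracellular (z > z0).

## Pore-lining residues and logos

A residue lines the pore when some heavy atom lies within a margin of a
profile sphere surface (| |x − c| − (r + vdw) | ≤ margin); the default
margin 1.4 Å is the water-probe radius, the natural contact criterion.
Residues are ordered by the axial coordinate of their closest-approach
atom, cytoplasmic first; heights are quantized to 1e-6 Å before the
residue-number tie-break so exact ties are broken deterministically under
floating-point noise. Note the ordering is only as reproducible as the
profile itself: rigid-motion invariance holds for the lining *set*
exactly and for the ordering up to permutations of near-equal heights.

Logo columns are the alignment columns of the lining residues via an
ungapped-reference mapping; frequencies exclude gaps from the
denominator, and information content is log₂20 − H bits. The packaged
51-position mapping for AQP2 is a constructed surrogate (labelled
synthetic in its filename and header): its anchor rows are the documented
residue↔position pairs, the filler rows are plausible but not derived
from a published figure. Deriving the full mapping from scratch requires
the experimental coordinates and a family alignment.

## Contacts, clashes, salt bridges

Cutoffs are the standard values of the contact-analysis literature:
8.0 Å between any heavy atoms for a contact, 4.5 Å between apolar
carbons/sulfurs for a hydrophobic contact, 4.0 Å between charged-group
nitrogens/oxygens of oppositely charged side chains for a salt bridge
(Arg NH1/NH2/NE, Lys NZ, His ND1/NE2 vs Asp OD1/OD2, Glu OE1/OE2). Apolar
atoms are side-chain C/S not bonded to N or O. A clash is a vdW overlap of
at least 0.3 Å outside the covalent exclusions, aggregated per residue
pair with the maximum overlap; the clash set is monotone in the threshold.
All engines agree with brute-force double loops on random fixtures
(oracle-equivalence tests).

Wild-type/mutant diffs are restricted to contacts involving the mutated
residue and, for packing conclusions, to the hydrophobic/salt-bridge
sub-types — the loose 8 Å contact rarely changes under a single side-chain
substitution and would mask real packing losses.

A proline is flagged helix-destabilizing when introduced anywhere in an
annotated helix except its two N-terminal positions (prolines are
tolerated helix starters).

## Electrostatics

The linearized Poisson–Boltzmann equation is solved by red–black
successive over-relaxation (ω = 1.8) on a 7-point stencil, converged to a
maximum update below 1e-4 kT/e, with two-pass focusing: a coarse solve on
the padded bounding box (spacing 1.5 Å, analytic Debye–Hückel boundary)
providing Dirichlet boundaries for a fine solve (spacing 1.0 Å). The
dielectric is two-valued — 1.0 inside the vdW spheres, 80.0 outside, no
reentrant surface — and the Debye term acts in solvent only (default
ionic strength 0). Charges are formal ±1 at side-chain charge centres
rather than force-field partial charges. These simplifications affect
absolute magnitudes, not the sign and locality of surface-potential
changes, which is what the comparison reports (mean/extreme Δφ over
solvent nodes within a radius of the mutated site). Against the analytic
Coulomb potential in uniform solvent the solver is within ~1% at 5–10 Å
(asserted at 5%); superposition and charge-linearity hold to solver
tolerance.

## Defect classification

Evidence per mutation: topology label; phosphosite proximity (window ±4
residues, covering regulatory serines 1–4 positions away from known
C-tail sites); loss of a C-tail salt bridge; helix-proline flag;
mutation-induced clash scores (mutant minus wild-type, clipped at zero,
split intra-/inter-monomer); counts of lost packing contacts by scope;
pore-lining membership and maximum sustained narrowing with its side.

The cascade, first match wins:

1. **signal loss** — C-tail site and (near phosphosite or lost C-tail
   salt bridge); trafficking signals have no transmembrane context, so
   this precedes the steric rules;
2. **monomer folding** — helix proline, or intra-monomer clash score
   ≥ θ_clash, or ≥ 2 intra-monomer contacts lost;
3. **tetramer assembly** — ≥ 2 inter-monomer contacts lost or
   inter-monomer clash score ≥ θ_clash;
4. **pore features** — pore-lining site with narrowing ≥ θ_pore;
5. else **unclassified**.

Folding outranks pore because a pore-lining residue whose substitution
also jams against its own monomer destabilizes the fold — narrowing is
then a symptom, not the defect. Defaults: θ_clash = 0.25 Å² of summed
squared overlap (≈ one 0.5 Å overlap), θ_pore = 0.3 Å over ≥ 3 slices.
These are gap-filling defaults exposed in the thresholds object; the
qualitative rules, not the exact values, carry the science. `classify` is
a pure function of (evidence, thresholds); rule-order monotonicity
(lowering θ_pore never flips a folding or signal verdict) is tested.

"Impaired metal binding" exists as a catalog category but is never
auto-assigned: detecting it would require metal-site annotation, and such
sites also admit folding/assembly readings; records may carry the label
as packaged data.

## Synthetic data: what it emulates and what it does not

The generators produce geometric test objects with planted ground truth:

* **ideal helices** — NeRF-built backbones at α-helical torsions
  (φ = −57°, ψ = −47°), template side chains; CA–CA 3.80 Å, rise
  ≈ 1.5 Å/turn emerge rather than being imposed;
* **channel walls** — pseudo-atoms (carbon-typed, configurable vdW)
  tiling a surface of prescribed radius R(z) at ~1 atom/Å²; expected pore
  radius R(z) − vdw is the analytic oracle; too-sparse packing (mean
  spacing > 2×vdW) is rejected as an unclosed wall;
* **helix-bundle channels** — n helices on a ring, a residue optionally
  substituted and spun to face the axis (planted narrowing);
* **interface tetramers** — C4 of a two-helix unit with a leucine spun
  across the monomer–monomer interface at a ring radius where it forms
  hydrophobic contacts with no vdW overlap, so shortening it is a pure
  packing loss;
* **tailed bundles** — a detached C-tail segment with an arginine and a
  serine phosphosite two residues downstream;
* **toy alignments** — i.i.d. uniform columns with planted conserved
  columns.

All generators are deterministic under a seed. They emulate the geometry
the analyses measure — wall radii, packing contacts, interface topology,
tail signals — and none of the physics they do not: no membrane, no
solvent, no realistic sequence composition, no crystallographic noise,
no NPA/ar-R chemistry. A passing suite therefore demonstrates that each
analysis recovers planted geometric ground truth and agrees with
independent oracles; it does not validate predictions on experimental
structures, which require the user-supplied PDB entries under
`data/structures/` (the corresponding checks fail with an explicit
message until those are present).

## Problem sizes

The default suite and the acceptance script run entirely on desk-scale
objects: channel walls of ~2,500 pseudo-atoms profiled at 0.5 Å steps,
bundles of 6–8 helices (~550–800 atoms), PB grids of ≤ 50³ nodes, and
60-atom random clouds for the brute-force oracles. These sizes keep every
oracle comparison exact or near-exact while the whole pipeline runs in
seconds.

## Known limitations

* Rigid-backbone mutagenesis cannot model substitutions that are
  accommodated by backbone shifts; its clash scores are upper bounds on
  strain.
* The slice-plane constraint of the sphere search underestimates radii in
  strongly tilted or kinked channels.
* Formal charges and a vdW dielectric boundary limit electrostatics to
  sign-level statements.
* The classifier's thresholds are calibrated defaults, not fitted
  parameters; categories for borderline evidence (single lost contact,
  0.2 Å narrowing) default to `unclassified` rather than guessing.
* The packaged 51-position mapping and the AQP2 helix boundaries are
  documented surrogates/approximations (see file headers); analyses that
  depend on their exact content are labelled accordingly.
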