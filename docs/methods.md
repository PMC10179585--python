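# Methods

## The pipeline in one paragraph

A disordered peptide is represented by a library of conformers generated by
blockwise excursion sampling (BES). A ligand is docked once against each
conformer (by an external engine; this package parses the engine's output),
near-degenerate poses are retained by a binding-affinity-gap rule, and
per-residue contact statistics over all retained complexes identify binding
hot spots. Geometric classifiers then label the noncovalent interaction
types behind those contacts, and standard trajectory observables (RMSD,
radius of gyration, SASA, distances, hydrogen-bond counts) quantify the
stability of bound complexes in follow-up simulations.

## Blockwise excursion sampling

An *excursion chain* alternates two kinds of blocks over a pluggable energy
model:

- a **simulated-annealing block** starts at a block-specific peak
  temperature and cools monotonically to the base temperature, carrying the
  chain into a new basin; peak temperatures default to 700, 600, 500, 400,
  350 K over a five-block chain, with a linear cooling schedule (an
  exponential schedule is available);
- a **relaxation block** runs constant-temperature dynamics at the base
  temperature (default 300 K) and records frames.

Each relaxation block contributes exactly one representative: every frame in
the tail *window* of the block is rigidly superposed (Kabsch) onto the first
window frame, the coordinate mean is taken, and the frame with the smallest
all-atom mass-unweighted RMSD to that mean is selected (ties go to the
earliest frame) and then energy-minimized with scipy's conjugate-gradient
minimizer. Block k+1 starts from block k's minimized representative. Chains
are independent, all start from the same extended structure, and chain seeds
derive deterministically from the base seed (`seed XOR
Knuth-hash(chain_index)`, recorded in the library manifest), so a library is
reproducible byte for byte.

Time is measured in integrator steps, not physical time. The default window
covers the final 5/6 of a relaxation block — the convention of discarding
the first sixth as re-equilibration after the anneal. The full protocol size
is 2000 chains x 5 blocks = 10,000 representatives; the
`ExcursionConfig.desk_scale` constructor keeps that accounting while using
20 SA steps, 24 relaxation steps (window 20) and a 20-iteration minimizer
cap per block, which builds the complete 10,000-member library on a
42-bead chain in a few minutes on one CPU. Acceptance runs and the
full-scale tests use exactly these sizes.

### Dynamics and the toy potential

The integrator is overdamped Langevin
(`x += -dt/gamma * grad E + sqrt(2 kB T dt / gamma) * xi`) with a per-bead
step-length cap (default 0.75 A) for stability on stiff repulsive cores; a
Metropolis single-bead Monte Carlo sampler is available as a fallback via
`integrator="metropolis"`. Determinism is per-seed in both.

The default system is a coarse-grained bead-per-residue chain:

    E = sum_bonds k_bond (r - r0)^2            k_bond = 5 kcal/(mol A^2), r0 = 3.8 A
      + sum_{|i-j|>=2} eps (sigma/r)^12        eps = 1 kcal/mol, sigma = 4.0 A
      + sum_dihedrals k_d (1 + cos phi)        k_d = 0.5 kcal/mol

The r0 = 3.8 A bond length is the CA–CA virtual bond of a trans peptide;
sigma = 4 A gives residue-sized excluded volume; the dihedral term makes
extended (trans) states the bonded minimum so compact conformers arise from
thermal exploration rather than attraction. Near-collinear dihedrals are
treated as trans with zero torque (their torsion angle is undefined). The
gradient of the dihedral term is taken directly on cos(phi) =
(b1 x b2)·(b2 x b3) / (|b1 x b2||b2 x b3|), which avoids signed-angle
conventions; a finite-difference consistency test (relative error < 1e-4)
guards the implementation. The fused energy+gradient kernel is
numba-compiled when numba is importable, with a bit-identical pure-python
fallback that also serves as an independent cross-check in the tests.

This potential is a desk-scale test system. It does not model hydrogen
bonding, side-chain chemistry, solvent, or realistic peptide energetics, so
a passing library build demonstrates the *protocol* (block structure,
representative selection, accounting, determinism) — not that the sampled
ensemble resembles any real peptide's.

## Docking interface

The search box is axis-aligned in the receptor frame: centre at the
unweighted heavy-atom centroid (a mass-weighted toggle exists, and
`heavy_only=False` admits hydrogens), half-edge per axis equal to the
maximal atomic excursion plus a margin (default 12 A), so every considered
atom keeps at least the margin from every face. Result files follow the
`<receptor>__<ligand>.pdbqt` pattern; assembly never reorders poses —
files whose affinities violate Vina's best-first order are flagged
(`rank_order_ok = False`) for the validation report. The external-engine
hook substitutes box and path placeholders into a shell command template
and does nothing else; parsing stays in `structure_io`.

## Pose selection

With dG_1 the top pose's affinity, pose k is retained iff
|dG_k - dG_1| <= cutoff; the comparison is inclusive (the phrase "within
the cutoff" is read as <=) and carries a 1e-9 kcal/mol tolerance so that
decimal gaps landing exactly on a decimal cutoff are not dropped by binary
floating point. The stored `delta_delta_g` is the magnitude of the gap
(the raw top-minus-lower difference is <= 0), so cutoffs are positive.
Duplicate best affinities: the first pose in the file is "top"; later
equal-affinity poses are lower-ranked with ddG = 0 and trivially retained.
No pose deduplication is performed. Selected-set sizes are reported per
cutoff as "set-1", "set-2", ... in cutoff order; totals are non-decreasing
in the cutoff by construction.

## Contact statistics

A residue is a binding residue of a complex iff the minimum heavy-atom
distance between the residue and the ligand is <= the cutoff (inclusive,
with a 1e-9 A tolerance); hydrogens are ignored on both sides. Per-residue
minimum distances are computed once per complex with a cKDTree nearest-
neighbour query, which answers membership at every cutoff of the ladder
simultaneously and is tested against an O(N^2) all-pairs oracle.

Default counting is binary per (complex, residue): the table cell is the
number of selected complexes in which the residue is a binding residue.
An `atom_pairs` mode instead counts all in-cutoff heavy-atom pairs, for
analyses that weight by contact surface. Receptor coordinates are the
docked rigid conformer's; no re-minimization. Hot-spot ranking sorts by
count descending, ties broken by residue number ascending; the window
share is (counts in window) / (all counts), with 0/0 defined as 0.

## Interaction geometry

The classifier thresholds live in one `InteractionCriteria` object. The
defaults follow common structural-biology practice and are the package's
own choices — the underlying interaction *types* are standard, but no
universal threshold values exist:

| interaction | acceptance (defaults) |
|---|---|
| hydrogen bond | D···A <= 3.5 A and D–H–A >= 130 deg (distance-only mode available) |
| pi–pi parallel | centroid distance <= 5.5 A and interplanar angle <= 30 deg |
| pi–pi T-shaped | centroid distance <= 6.0 A and interplanar angle >= 60 deg |
| XH–pi (X = C,N,O) | H–centroid <= 3.0 A, in-plane offset <= ring radius + 0.5 A, X–H to H–centroid angle <= 60 deg |
| lone-pair–pi (O/N) | atom–centroid <= 3.5 A and <= 25 deg off the ring normal |

Interplanar angles are folded to [0, 90] degrees so the sign ambiguity of
plane normals cannot flip a class. Every emitted record stores the geometry
it was accepted on, and `audit_record` re-checks it against the criteria —
a self-consistency property enforced in the tests, which makes results
reproducible for any threshold choice.

Protein rings come from fixed residue templates (PHE/TYR six-membered, HIS
five-membered, TRP both); ligand rings come from an explicit annotation or
from cycle perception (networkx minimum cycle basis) on a bond table,
keeping 5/6-cycles that are planar within 0.1 A. That tolerance separates
aromatic rings (planar to < 0.01 A) from saturated half-chairs such as the
flavan pyran ring (~0.25–0.5 A deviation); RDKit's aromatic ring perception
on catechin-class molecules is the independent oracle in the tests. Donor
and acceptor typing uses template tables for the 20 amino acids; ligands
require an explicit annotation (no automatic protonation).

## Trajectory metrics

All metrics are invariant under global rigid motion (tested). Kabsch RMSD
is mass-unweighted and computed by SVD with a proper-rotation correction;
the reference is the first frame by default. Radius of gyration,
inter-group minimum distances and end-to-end distances are reported in nm
(coordinates are Angstrom internally). SASA is Shrake–Rupley with a
golden-spiral point set (default 960 points, 1.4 A probe) over Bondi-style
van der Waals radii shipped with the package (`VDW_RADII`, tagged
"bondi-1964"); per-residue values sum exactly to the total, and the
isolated-sphere analytic limit is reproduced within 1%. Hydrogen-bond
series reuse the interaction-geometry detector frame by frame. No solvent
is ever simulated: solvent-involving hydrogen-bond modes require explicit
solvent coordinates in the trajectory and otherwise error, so
solvent-related observables are reproducible in form only.

The per-residue/ligand "average distance" is the frame-averaged *minimum*
heavy-atom distance by default (a centroid-based alternative can be
assembled from the same masks); minimum distance is the stricter and more
common choice for contact persistence.

## Synthetic fixtures

`make_toy_peptide` builds one CA bead per residue with an amyloid-beta-like
42-residue sequence (so labels TYR10, PHE19, PHE20 are meaningful),
extended (planar zig-zag, 120-degree bead angles), collapsed (spherical
spiral) or random-walk geometry. The toy ligand is a rigid 14-heavy-atom
biphenyl-like fragment with two annotated rings, two hydroxyl donors and
two acceptor oxygens. Pose sets are written in the Vina output dialect
with affinities built from a configurable non-negative gap distribution;
planted contact bands are satisfied by direct rigid placement — the contact
atom is the extreme heavy atom along the ligand's principal axis, oriented
away from the receptor, which guarantees every other ligand atom lies at or
beyond the target distance from the anchor residue. Unsatisfiable band
combinations raise rather than silently fail. Interaction fixtures realize
each classifier's acceptance geometry exactly and ship a "negative twin"
violating exactly one threshold; the cross-classification matrix over the
five kinds is diagonal by construction and by test.

What the fixtures do *not* emulate: real docking score landscapes, ligand
flexibility, receptor side chains, or solvent. Passing the planted-signal
suites shows the detectors are correct, not that the statistics transfer to
any particular real system.

## Problem sizes and numerical choices

- Full-scale runs (acceptance script and ensemble tests) use 2000 chains x
  5 blocks on a 42-bead chain with the desk-scale step counts above; the
  library build takes ~4 minutes and the 10,000-run pose accounting ~1
  minute on one CPU.
- Inclusive boundaries everywhere (distance = cutoff counts; gap = cutoff
  selects), each with a 1e-9 absolute tolerance against binary-float
  artefacts.
- Representative-selection ties break to the earliest frame within 1e-9 A
  of the minimum RMSD.
- The conjugate-gradient minimizer result is discarded in favour of the
  unminimized frame in the (pathological) case where the line search ends
  above the starting energy, preserving the invariant
  `minimized_energy <= frame energy`.
- Element inference for PDB files without an element column takes the first
  alphabetic character of the atom name after stripping leading digits;
  files with genuine two-letter elements should carry the element column.
  Alternate locations other than blank/"A" are dropped for deterministic
  heavy-atom sets.

## Known limitations

- The sampler's toy potential is not a force field; libraries are
  structurally diverse but not thermodynamically meaningful ensembles.
- Only the Vina *output* PDBQT dialect is parsed; AutoDock map/flexres
  files are rejected by design.
- Ligand donor/acceptor/ring annotation is manual; there is no automatic
  protonation or bond-order perception from coordinates.
- Contact-table semantics ("binary" vs "atom_pairs") change absolute
  counts; cross-study comparisons must fix the mode.
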