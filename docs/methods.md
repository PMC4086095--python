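# Methods

`pepsurf` predicts peptide-binding regions on a protein surface with no
prior knowledge of the binding site.  The pipeline has three stages:
peptide conformer ensemble generation, exhaustive coarse-grained
rigid-body docking over the whole protein surface, and per-residue
interface-propensity scoring over the top-ranked poses.  This note
records the models, the parameters that matter, the numerical choices,
and what the synthetic test system does and does not demonstrate.

## Coarse-grained representation

Proteins and peptides are reduced to beads: every backbone heavy atom
(N, CA, C, O) is kept as its own bead, and each side chain contributes
up to two pseudo-beads placed at the centroid of a heavy-atom group.
Glycine has none; side chains with at most four heavy atoms form one
group; larger side chains are split at the first branch point into a
proximal and a distal group (e.g. ARG: CB-CG-CD | NE-CZ-NH1-NH2).  This
keeps every residue between 4 and 6 beads and gives a deterministic,
chemistry-respecting partition.

Bead types index a pair-parameter table loaded from
`src/pepsurf/data/forcefield.yaml`.  The shipped table is a
**self-consistent generic stand-in**, not a published parameterization:
per-type diameters scale with group size (2.9-4.6 Å), well depths are
of order 1 kcal/mol and deeper for large apolar/aromatic groups, pair
parameters follow Lorentz-Berthelot-style combination (arithmetic mean
sigma, geometric mean epsilon), and like-charged side-chain bead pairs
are flagged purely repulsive.  Formal charges sit on the distal
side-chain bead of ASP/GLU (−1) and LYS/ARG (+1); histidine and chain
termini are neutral by default.  Users with access to a published
reduced-force-field table can drop in their own file with the same
schema; its SHA-256 checksum is logged at load time and recorded in the
run manifest.

## Interaction energy

The receptor–peptide energy is a sum over bead pairs of a soft 8-6
Lennard-Jones term and a screened Coulomb term:

    E_LJ(r)   = ε [ (σ/r)^8 − (σ/r)^6 ]
    E_elec(r) = 332.0636 q_i q_j / (ε₀ r²),   ε(r) = ε₀ r,  ε₀ = 15

The 8-6 form has its minimum at r_min = σ√(4/3) with depth −27ε/256
(both used as closed-form oracles in the tests).  Pairs flagged
repulsive use the standard purely repulsive variant (E + 2|E_min| for
r < r_min, −E beyond), which is C1-continuous and non-negative
everywhere.  Below r_min/2 the combined pair potential continues
linearly with matched slope: blind-docking starts guarantee clashed
orientations, and the linear core keeps the energy finite and the
gradient defined there.

Defaults: distance cutoff 20 Å, distance-dependent dielectric ε₀ = 15/Å,
Coulomb constant 332.0636 kcal·Å/(mol·e²).  Neither a cutoff nor a
dielectric is prescribed by the protocol this package follows, so both
are configurable and logged.  For desk-scale systems all pair
parameters are precomputed into dense matrices and evaluated by a fused
compiled kernel; a KD-tree neighbor-list path handles large systems and
a pure-numpy all-pairs path serves as the reference in tests (the three
agree to ~1e-9 kcal/mol).

## Conformer generation

The generator fills the pipeline slot of a de novo peptide structure
predictor with a transparent, seeded sampler; it is *not* a structure
predictor.  Backbone dihedrals are drawn from residue-specific
Ramachandran basins (helix −63/−43, sheet −120/135, polyproline-II
−75/150, left-handed 57/47; glycine with doubled widths and real
left-handed weight, proline φ restrained to −65).  Helix formers
(A, L, E, M, Q, K, R, H) weight the helical basin at 0.45; sheet
formers (V, I, T, Y, F, W, C) the extended basin at 0.45; the rest are
near-uniform.  Coordinates are chained with standard trans-peptide
geometry (N-CA 1.458 Å, CA-C 1.525 Å, C-N 1.329 Å, ω = 180°), which
fixes consecutive CA-CA distances at ~3.80 Å.  Side-chain pseudo-beads
are projected from the backbone along the ideal CB direction at
group-typical distances.  Chains with any bead pair closer than 2.2 Å
across residues separated by ≥2 in sequence are rejected and resampled
(budget: 100 attempts per requested conformer).  Each conformer is
scored with the same coarse-grained pair potential applied
intramolecularly over residue-separated pairs.

By default 200 conformers are sampled and clustered greedily, best
score first, on superposed CA RMSD at a 2.0 Å threshold; the centroids
of up to the 20 lowest-score clusters enter docking.  The 2.0 Å
threshold is a declared default — no value is prescribed for this
stage.  A multi-model PDB ensemble from an external predictor can
replace the sampler entirely (capped at 20 models).

## Blind rigid docking

Start positions are placed on the offset surface at twice the peptide
radius (maximum bead distance from the conformer centroid) from the
receptor surface, about 10 Å apart.  The surface is the set of bead
centers offset by a configurable bead radius (default 0 Å, i.e. the
bead centers themselves).  Directions from the receptor centroid are
sampled on a golden-angle spiral, each projected onto the offset
surface by an inward march plus bisection (outermost crossing, so
pockets do not trap starts inside), the direction count chosen from a
hex-packing estimate of the offset-surface area, followed by a greedy
thinning pass at 0.7× spacing.  On a spherical test receptor this
yields nearest-neighbor spacings within [0.7, 1.5]× the nominal
spacing and positions at the analytic offset.

At each start, 260 orientations are tried: 13 axis directions (golden
angle spiral, first axis +z) × 20 evenly spaced rolls, giving a
deterministic, near-uniform cover of rotation space whose first element
is the identity.  Each (start, orientation) pair is relaxed by
quasi-Newton (L-BFGS-B) minimization over the six rigid-body degrees of
freedom, parametrized as an incremental rotation vector about the
conformer centroid (gradient via the right Jacobian of SO(3)) plus a
translation, with analytic force and torque.  Convergence: projected
gradient inf-norm < 0.05 kcal/mol/Å (default) or 500 iterations; a
configurable evaluation budget caps pathological line searches.  If
the minimizer ever returns a worse energy than the start, the start
pose is kept, so descent holds by construction.  Non-finite start
energies discard the pose with a log entry.

Starts are independent; the optional process pool partitions them by
index and the merged output is bit-identical for any worker count.
Poses are ranked by ascending energy, with exact ties broken by
(conformer, start, orientation) indices so the ranking is total and
deterministic.

## Pose redundancy filtering

Ranked poses are filtered by an energy-ordered leader pass: a pose
whose docking-frame RMSD (no re-superposition — re-fitting would merge
poses at different sites) to a recent cluster representative is below
1 Å is discarded; otherwise it founds a new cluster.  Only the latest
50 representatives are compared, keeping the pass O(n).  Poses of
different conformers are compared over CA beads (same sequence, equal
counts).  The pass runs once per docking simulation and once more on
the aggregated ranking to remove cross-conformer redundancy.

## Interface propensity

For each of the 50 best non-redundant poses, receptor residues with at
least one bead strictly within 5 Å of any posed peptide bead are at
the interface.  The propensity of residue r is

    p_r = 100 · Σ_{i=1..50} p_r^i / 50,    p_r^i ∈ {0, 1}

so every p_r is an integer multiple of 2 (or of 100/n when fewer than
50 poses survive; the normalization then uses the count actually
scored).  Contacts are computed on beads by default — backbone beads
are true heavy atoms and pseudo-beads proxy side-chain heavy atoms —
with an optional all-atom receptor mode and an alternative
CA-only/6.5 Å mode for comparison against site predictors that return
one point per residue.  Propensities are written into the temperature
factor field (columns 61–66) of a PDB copy of the receptor, as a
per-residue table, and alongside the ranked poses as a multi-model PDB
plus a viewer script.

## Synthetic reference complexes

`evaluate.make_synthetic_complex` builds a seeded test system with a
known answer: alanine residues are packed on concentric shells 4 Å
apart (residue spacing 4.2 Å) to form a compact quasi-spherical
receptor; a peptide conformer sampled from the given sequence is
planted with its centroid 5 Å below the outer shell, and receptor
residues with any atom within 3.0 Å of a peptide bead are removed,
carving a groove complementary to the planted conformer.  The native
interface follows the same 5 Å rule used for predictions.

What the fixture emulates: a single, well-formed, geometrically
complementary binding groove on an otherwise featureless convex
surface.  What it does not: chemical heterogeneity of real binding
sites, competing pockets, conformational change on binding, crystal
contacts, or the size and shape diversity of real proteins.  Passing
the recovery test therefore demonstrates that the search, ranking,
clustering and scoring machinery can find and highlight a site that the
energy model genuinely favors — not that the generic force field
reproduces experimental binding preferences.

### End-to-end study conditions

The recovery experiment used by the test suite and the acceptance
script docks the *bound* conformer (the same conformer the groove was
carved for, in its generator frame) blindly over the whole surface of
ten seeded complexes built from the 4-residue peptide ATVS on receptors
of 8 Å outer radius, at 12 Å start spacing with 60 orientations per
start, a 25 Å energy cutoff, and a 0.005–0.01 kcal/mol/Å gradient
tolerance.  These problem sizes keep a ten-complex experiment around
five minutes on one core.  Bound-conformer docking is the standard way
to isolate the search-and-scoring question from conformer-generation
accuracy; with a sampled ensemble instead, recovery additionally
depends on the sampler producing a groove-compatible shape, which the
fixture's tightly carved walls (3 Å clearance) deliberately do not
forgive.  The looser-than-default gradient tolerance and wider cutoff
are needed because starts sit at twice the peptide radius from the
surface, where the soft 8-6 attraction of the small neutral test system
is shallow; production runs on real proteins retain the logged
defaults.  Reported outcomes: fraction of seeds whose top-ranked pose
centroid lands within 5 Å of the planted site, the fraction of native
interface residues contacted by the ten best poses, and the mean
propensity difference between planted-interface residues and the rest.

## Numerical and design notes

- All randomness flows through `numpy.random.default_rng` seeds;
  repeated runs and any worker count are byte-identical.
- Quaternions are stored normalized ((x, y, z, w) order); rotation-
  vector increments are re-anchored at each minimization, so no
  renormalization drift accumulates.
- Pose RMSD ties and propensity ties break on residue/file order,
  never on floating-point hashing.
- PDB reading keeps the first MODEL, the first altloc, all protein
  chains; hydrogens and waters are stripped; MSE is mapped to MET;
  other non-standard polymer residues are rejected.  Peptide sequences
  must be 4–36 standard residues.
- Degenerate inputs (empty pose lists, empty native interfaces,
  receptors under 4 beads, zero contact cutoffs) raise explicit errors
  rather than returning silent defaults.

## Known limitations

- The shipped force-field table is generic; absolute energies are in
  kcal/mol only nominally, and real-protein accuracy claims would
  require a published parameter set dropped into the same schema.
- Docking is rigid; peptide flexibility is represented only through
  the ensemble of up to 20 conformers, and receptor flexibility not at
  all.
- The conformer sampler covers Ramachandran basins but has no
  sequence-specific long-range structure signal.
- No solvation or desolvation term; electrostatics use a simple
  distance-dependent dielectric.
- Propensity smoothing/patch detection over the surface is out of
  scope.
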