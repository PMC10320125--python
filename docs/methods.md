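# Methods

## Pose model

A pose is (t, q, ν): translation of the ligand heavy-atom centroid (Å),
unit quaternion rotation about that centroid, and M anisotropic-network-
model amplitudes (dimensionless). The centroid is the rotation center so
translation and rotation stay nearly decoupled during optimization.
Quaternions are kept sign-canonical (w ≥ 0; at w = 0 the first nonzero
component positive), which identifies the antipodal pair q/−q and makes the
pose metric well defined. The metric concatenates [Δt, w_q·Δq, Δν] and
takes the Euclidean norm; w_q = 10 Å per unit quaternion distance, so a
large reorientation "costs" roughly a 10 Å displacement. All neighborhood
tests, movement steps and step sizes live in this one metric space.

ANM flexibility: Cα-only elastic network, uniform springs, 15 Å cutoff;
the Hessian's six near-zero eigenvalues (rigid-body motions) are skipped
and the next M = 10 (default) eigenvectors form the basis, scaled 3 Å per
unit amplitude, amplitudes clamped to |ν_k| ≤ 3. Each residue's atoms
rigidly follow its Cα displacement — a cheap approximation that avoids
full-atom mode extension. Degenerate geometries are handled explicitly:
connectivity is a graph test on the cutoff adjacency (a collinear chain is
connected yet has more than six zero modes, so counting zero eigenvalues
cannot serve as the connectivity check). Membrane receptors refuse
flexibility: elastic deformation of the slab-embedded partner would break
the geometry the membrane filter relies on.

## Sampling and optimization

Swarm centers: every solvent-accessible heavy atom (Shrake–Rupley test
points, probe 1.4 Å, 92 deterministic golden-spiral directions) proposes a
center 10 Å along its outward radial direction; candidates are greedily
thinned to a 10 Å minimum spacing, visited by descending distance from the
centroid with ties broken by atom serial. The swarm count therefore tracks
receptor size and shape. A user-requested count subsamples evenly — except
under restraints, where a reduced budget keeps the swarms closest to the
restraint patch (spending swarms far from a declared interface would defeat
the purpose of declaring it).

Each swarm holds 200 glowworms by default (50 in the desk-scale
benchmarks). Initial translations are uniform in the 10 Å swarm ball;
orientations are uniform on SO(3) (Shoemake) unless ligand restraints
exist, in which case each agent draws one receptor/ligand restraint pair,
rotates the ligand so the restraint residue faces the receptor patch, and
is jittered by ≤ 15°.

GSO uses the canonical update rules with ρ = 0.4, γ = 0.6, β = 0.08,
n_t = 5, ℓ₀ = 5, r_s = 2 × swarm radius. Two constants deserve comment:

* **step size s = 0.5** pose-metric units (~0.5 Å per iteration). The
  textbook value 0.03 belongs to unit-scale benchmark functions; in a
  metric where agents start 5–20 units apart it permits at most 3 units of
  total movement in 100 steps — no refinement at all. Half an Ångström per
  step matches the translation strides used across this docking family.
* **initial vision r_s/2.** Starting at r_s makes the whole population one
  neighborhood at step 1, collapsing every swarm onto its single brightest
  agent; r_s/2 preserves several local optima per swarm. The value was
  selected by measuring search performance on generator seeds disjoint from
  any documented benchmark condition.

The movement phase is synchronous: neighborhoods, roulette targets and
steps are computed from a post-luciferin-update snapshot and applied
together, so results are independent of agent iteration order. One RNG
stream per swarm (seeded seed + swarm id) makes swarms independent and runs
bitwise reproducible; a non-finite objective value marks the agent −∞ so it
can never attract others. Per-step work is one objective call per agent
(no caching of unmoved poses — simpler, and any caching must not change
results).

## Scoring and restraints

Default potential: soft-core 12-6 LJ plus screened Coulomb, heavy atoms
only, 10 Å pair cutoff, distances clamped at 1 Å to keep early random
sampling finite. Per-element radii C 1.9 / N 1.7 / O 1.6 / S 2.0 / P 2.1
(default 1.8) Å; ε = 0.1 kcal/mol; ε_r = 15; k_c = 332 kcal·Å/(mol·e²).
Formal charges sit on the usual titratable atoms (Asp/Glu carboxylates
−0.5 each, Lys NZ +1, Arg NH1/NH2 +0.5, DNA OP1/OP2 −0.5). The raw score
is S = −E. Scoring functions are pluggable by name; the engine only needs
one finite real per pose.

Restraint satisfaction: a declared residue is satisfied when any of its
heavy atoms is within d_c = 5 Å of any partner heavy atom; receptor and
ligand restraints are pooled into one fraction f_sat (tracking the two
sides separately is a documented alternative; pooling keeps a single
threshold). The optimizer objective is J = S·max(f_sat, 0.01) for S > 0
and J = S/max(f_sat, 0.01) for S ≤ 0 — violation always hurts, whatever
the sign. Global ranking uses the raw S, not J: the bias shapes the
search, the reported energies stay physical. Final models need
f_sat ≥ 0.5 (default).

## Post-processing

Per-swarm clustering is one-pass BSAS on ligand anchor-atom RMSD (Cα, or
C1′ for DNA; no superposition, since all poses share the receptor frame):
agents visited by descending luciferin found a cluster iff farther than
4 Å from every existing representative, else join the nearest. Cluster
founders are the representatives; ranking is raw-score descending with
(swarm, glowworm) id tie-breaks. A final-relaxation hook exists with an
identity default; a geometry-refinement backend can be plugged in but none
ships.

## Synthetic data

The toy complex emulates a restraint-driven docking study with a known
answer. Receptor: 60 poly-alanine pseudo-residues per wall layer (two
layers, 3.6 Å apart) on a radius-12 Å spherical lattice; each residue is a
4-atom cluster (N/CA/C tangential triplet plus an inward O) so the wall is
solid at atomic resolution. Ligand: a 12-residue helix-like Cα/Cβ trace
whose radius tapers 1.6 → 3.0 Å along the chain, removing end-to-end
pseudosymmetry. The ligand is sunk 4 Å into the +z pole and the wall is
molded around it — every clashing cluster is pushed radially inward until
its closest approach equals 3.8 Å, the potential's pair optimum — and six
aperiodically spaced salt bridges (ligand Lys-like NZ, +1; receptor
Asp-like OD1, −0.5, embedded in the wall radially outward of each NZ) pin
the binding register the way real interfaces do. Each geometric feature
closes a decoy class a plainer construction admits: a sparse Cα-only shell
lets the ligand thread between atoms; an untapered helix docks flipped; a
shallow mold lets thin sections slide; without the bridges, tilted
in-groove poses score near-native. Interface residues within 5 Å across
the native interface are returned as ground-truth restraints, and the
native pose is the potential's optimum of the binding patch by
construction. Small seed-dependent lattice jitter (σ = 0.004 rad) makes
each seed a distinct but equivalent instance.

What the fixture does **not** emulate: side chains and their packing,
desolvation, conformational change on binding, or realistic score
roughness. Passing the recovery benchmark shows the sampling, biasing,
clustering, ranking and filtering machinery is correct — not that the
default potential would rank real complexes.

The extended-peptide builder places N/CA/C/O/CB with ideal bond internal
coordinates (NeRF chain construction) at φ = ψ = ω = 180°, giving the
characteristic 3.80 Å Cα–Cα spacing. The synthetic Fv is a poly-alanine
Cα pair of coils with chains H and L numbered 1..n so all six CDR windows
of every scheme are structurally present; it is a numbering fixture, not
an immunoglobulin fold.

## Benchmark scale and determinism

The documented desk-scale recovery condition is 5 swarms × 50 glowworms ×
100 steps (≈75 s on one CPU), generator and run both seeded 42: the rank-1
model lands ~2 Å Cα-RMSD from the native pose. At this budget success is
seed-dependent — roughly half of other seeds leave the rank-1 model on a
5–9 Å shoulder of the funnel with the narrow native basin unsampled;
larger budgets (more swarms or agents) recover it. This is the expected
behavior of a stochastic global search at small population sizes, and the
reason the protocol samples many swarms in production settings. All
stages are deterministic given the seed; swarm snapshot files store floats
at 17 significant digits so the file-staged pipeline reproduces the
in-memory trajectories bit for bit.

## Known limitations

* Rigid side chains; flexibility is backbone-collective only.
* The default potential has no desolvation, hydrogen-bond or statistical
  terms (the plug-in interface is the intended extension point).
* Single-plane membrane (the slab cushion supplies thickness); no bilayer
  physics.
* Antibody inputs must already be numbered; no renumbering is performed.
* Kabat heavy-chain insertion conventions (35A/35B) are simplified to the
  numeric window plus any insertion codes inside it.
* mmCIF input and multi-model NMR handling beyond the first model are out
  of scope.
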