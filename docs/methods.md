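# Methods

## The model

A residue type is an atom graph with *ideal internal coordinates*: every atom
carries a bond length, bond angle and dihedral with respect to three
previously built reference atoms, so a Cartesian conformation is a
deterministic function of the torsional degrees of freedom alone
(natural-extension / NeRF placement, build order = file order).  Bond lengths
and angles never relax; ring internal coordinates are fixed, so distinct ring
puckers (e.g. the two 2-indanyl-glycine conformers) are distinct residue
types.  The unit of conformational sampling is the **dipeptide**: the residue
with an acetyl cap on the N-terminus and an N-methyl amide cap on the
C-terminus, which exposes every φ/ψ-dependent side-chain–backbone contact
while excluding everything else.  Both peptide-bond ω's are fixed trans
(180°).  All angles are degrees, canonical interval (−180, 180]; χ's with a
declared period of 180° (symmetric termini) are additionally folded into
(−90, 90].

Ideal geometry in the shipped fixtures is Engh–Huber-like (N–CA 1.458 Å,
CA–C 1.525 Å, N–CA–C 111.2°, …) with CHARMM27-style atom typing.
L-chirality follows the CCD ideal-coordinate convention
(dihedral(CB, CA, N, C) = −120°).  Methyl and hydroxyl hydrogens are placed
staggered relative to a sibling substituent and do **not** relax — a known
limitation discussed below.

## Energy

Two unweighted molecular-mechanics terms are computed from a conformation:

* torsion: `E = Σ_paths Σ_terms K (1 + cos(nχ − θ))` over every distinct
  bonded 4-atom path, parameters looked up CHARMM-style (exact atom-type
  quadruple in either direction, then wildcard `X t2 t3 X`); a missing entry
  is an error naming the quadruple;
* Lennard-Jones: `E = ε[(r_min/d)¹² − 2 (r_min/d)⁶]` over all atom pairs
  separated by three or more chemical bonds (graph distance on the bond
  graph), combination rules ε_ij = √(ε_i ε_j), r_min,ij = r_i/2 + r_j/2.
  The term is split at the pair minimum: for d < r_min the attractive branch
  is pinned at −ε and the repulsive branch carries the excess; the two
  branches always sum to the raw value.  1–4 pairs use the standard
  parameters (no special 1–4 set), and no distance cutoff is applied to
  dipeptides.

Weighted totals are plain dot products of term values with a weight set; the
shipped default is the fitted modified set (torsion 0.27, intra-rep 0.32,
intra-atr 0.54, inter-rep 0.63, inter-atr 0.80, unfolded 0.90).  Library
generation, however, scores with the **unweighted** torsion + LJ sum: the
Boltzmann conversion `P ∝ exp(−E/k_B T)` presumes physical energies in
kcal/mol, and k_B T = 0.5917 kcal/mol (298 K) is used throughout.

χ-gradients are central finite differences (step 0.01°), guarded against
interatomic distances below 0.1 Å where the LJ slope is numerically useless.

## Library generation

Per (φ, ψ) bin (default 10° grid → 1296 bins):

1. seed conformations at the Cartesian product of per-χ grids (default 5°,
   respecting each χ's period);
2. 25 outer steps of steepest descent on the χ's only (unit-normalized
   gradient direction, Armijo backtracking from a 5° trial step, shrink 0.5)
   — deliberately *local*, so each seed falls into its nearest well;
3. circular K-means (assignment by the χ-vector distance
   √Σ min-image Δχ², centroids per-χ circular means, empty clusters reseeded
   at the farthest point, convergence or 500 sweeps).  Cluster count and
   starting centroids are per-residue inputs; shipped defaults are the
   products of {−60, 60, 180} per sp³ χ and {±90} per aromatic χ;
4. the rotamer of each cluster is its lowest-energy member (ties broken by
   smallest χ1, then χ2, …), *not* the centroid;
5. per-χ standard deviations: scan each χ alone in 0.25° steps both ways and
   report the mean deviation at which the energy first rises 0.5 kcal/mol
   (linear interpolation, capped at 60° with a flat-direction flag);
6. cluster energies → probabilities by Boltzmann weight, normalized to 1
   within each bin.  The inverse map is E = −k_B T ln(P/P_max), so the most
   probable rotamer scores 0 and P = 0 clamps at 1e−16.

The pipeline contains no stochastic step; the recorded seed exists only to
pin hypothetical tie-breaks, and identical configurations give bit-identical
libraries.

### Counting distinct wells

`distinct_minima_count` is a clustering-free instrument: minimize from the
dense seed grid, then (a) discard endpoints that are not local minima along
every χ axis (seeds that started exactly on a barrier top have zero gradient
and never move; a 25-step budget can also leave stragglers on slopes), (b)
discard endpoints with interpenetrating atoms (any nonbonded pair closer
than 1.0 Å — descent through a hard clash can terminate inside an
unphysical geometry), then (c) merge the survivors with a 30° χ-distance
leader pass in ascending energy order and count the representatives.

**Known limitation.**  On the rigid-geometry landscape this count exceeds
the textbook well taxonomy for crowded side chains.  Because bond angles and
methyl-H torsions cannot relax, hard LJ walls develop shallow
"foot-of-wall" sub-wells (for the leucine dipeptide on a helix, e.g. a
~0.4 kcal/mol shelf near χ1 ≈ −136° between the gauche⁻ and trans wells)
and strained side chains retain thermodynamically empty wells (for
α-methyl-tryptophan, χ2 ≈ 0° wells at +16–19 kcal/mol that the α-methyl
clash effectively forbids).  The instrument therefore reports 14 wells for
leucine at (−60, −40) — the 9 canonical χ1×χ2 wells carrying essentially
all Boltzmann mass, plus shallow/strained artifacts — and 11–14 for
α-methyl-tryptophan instead of its 6 thermally relevant rotamers.
Alternatives were evaluated and rejected: CHARMM special 1–4 parameters
(introduces a new sub-well), short-range linearization of the repulsion (no
effect — the artifacts live at the foot of the wall, not in its core), and
barrier-based coalescence (transitive merging fuses genuine wells through
low corridors).  The K-means stage of the *library* pipeline is unaffected:
with the canonical cluster seeds the artifacts are absorbed into their
parent wells and the published well structure (9 leucine rotamers, 6
α-methyl-tryptophan rotamers, >90 % valine trans mass) is what the library
reports.

## Unfolded-state reference energies

The unfolded (reference) energy of a type is the ensemble average of its
unweighted per-term energies at the center of capped 5-mers, repacked per
fragment; the weighted unfolded energy is Σ_j w_j ⟨E_j⟩ with the folded-state
weights.  The backbone ensemble is a Ramachandran mixture — 40 % α at
(−63, −43) σ 10°, 40 % β at (−120, 130) σ 15°, 20 % uniform, each residue
independent — chosen as a minimal stand-in for fragments cut from real
structures: it reproduces the coarse occupancy of the basins but none of the
sequence- or neighbor-dependence of real coil, so unfolded averages here
calibrate the machinery rather than reproduce published reference values.
The sampler is pluggable: any (n, 5, 2) array of φ/ψ values can be
substituted.  Flanking residues default to alanine; repacking is
fixed-backbone.  Default ensemble size 500.  Inter-residue LJ pairs
contribute half to each participating residue, so residue terms sum to the
chain total.

## Packing and weight fitting

Packing operates on cached one-body and pairwise rotamer energies.
Simulated annealing uses a geometric ladder from 10 k_BT to 0.1 k_BT over 8
levels with N_pos·N_rot moves per level by default, Metropolis acceptance,
and best-seen bookkeeping (the returned state is the best ever visited).
Rotamer trials visit flagged positions in seeded random order and give each
the context-optimal candidate.  Small moves rotate one φ or ψ by up to 3°;
shear moves rotate φ(i) and ψ(i−1) oppositely.  The composed peptide design
loop (perturb → rotamer trials, every 100 cycles one pack-rotamers phase,
50 iterations) takes the energy model as a pluggable system builder.

Weight fitting maximizes `F = Σ_p ln softmax(−E/k_BT)[native]` — the
log-likelihood that each position's native type is lowest — which is the
functional form implied by "probability that the native residue scores lower
than all others"; it is invariant to per-position constant shifts and
strictly decreasing in the native energy.  Each round: particle swarm (20
particles, 50 iterations, inertia 0.72, cognitive/social 1.49, incumbent
kept in the swarm) then L-BFGS-B refinement of the free weights, bounded to
[0, 5] (published weight sets are positive).  Sequence recovery (fraction of
positions whose weighted argmin is native; ties are misses) gates
acceptance: improved → keep, else average element-wise with the previous
weights; 10 rounds by default.  Recovery is evaluated at the tensor level
(per-position argmin), not by full repacking — the algorithm is preserved
while the training data (a positions × types × terms tensor) can come from
any source, including the synthetic generator used in the tests.

## Numerical choices and degenerate inputs

* Probabilities written to library files are rounded to 4 decimals with a
  largest-remainder correction so every written bin still sums to exactly 1.
* The file reader canonicalizes φ = −180 rows to +180, renormalizes
  off-by-more-than-1e−6 bins with a warning, and trims trailing all-zero χ
  columns.
* K-means with more seeds than distinct minima still returns one rotamer per
  cluster (the reseeding rule guarantees non-empty clusters); zero-χ residues
  yield a single unit-probability rotamer per bin.
* Problem sizes in the shipped tests are chosen for quick feedback: coarse
  φ/ψ grids (90–180°) and 15–30° χ seeding wherever the assertion does not
  depend on the dense 5° protocol; the acceptance script runs the full-width
  5° protocol on single bins.

## Known limitations

* Rigid ideal geometry: no bond-angle strain relief, frozen methyl/hydroxyl
  spins except where declared as χ's — see the well-count discussion above.
* No solvation, hydrogen-bonding or electrostatic terms: rotamer libraries
  for short polar side chains will miss wells stabilized by side-chain–
  backbone electrostatics.
* The inter-residue LJ uses the same analytic form as the intra term, with
  no switching function; chains evaluated here are short.
* The unfolded ensemble is synthetic (see above); published reference-energy
  values are not reproduced, only the estimation procedure.
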