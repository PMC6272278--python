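# Methods

## The model

`cgdock` implements a coarse-grained lattice model of protein chains for
flexible protein–peptide docking. Each residue is reduced to up to four
pseudoatoms:

- **Cα**, confined to a simple cubic lattice with spacing 0.61 Å.
  Consecutive Cα atoms are joined by "virtual bonds" drawn from the set of
  integer vectors `v` with `29 ≤ |v|² ≤ 49`; exactly 800 such vectors
  exist, giving bond lengths between 3.28 and 4.27 Å around the canonical
  3.8 Å Cα–Cα distance and making lattice anisotropy negligible.
- **Cβ**, placed 1.53 Å from the Cα along a deterministic local axis
  (opposite the bisector of the two adjacent virtual bonds, tilted 35° out
  of the backbone plane; termini copy the neighbouring frame).
- a **side-chain center**, on the same axis at a residue-specific,
  rotamer-averaged distance (0 Å for glycine: its side-chain center is the
  Cα itself).
- a **hydrogen-bond center** per virtual bond, at the exact Cα midpoint.

Off-lattice pseudoatoms are pure functions of the local Cα geometry: they
"follow" the backbone and need no dynamics of their own.

Casting an off-lattice Cα trace onto the lattice uses a least-squares
beam-search walk (beam width 16): residue 1 is anchored at its rounded
lattice point and each later residue extends the beam with all 800 bond
vectors, keeping the lowest cumulative squared deviation while enforcing
the excluded-volume Cα hard core. The discretisation costs ≈ 0.3–0.35 Å of
mean coordinate error on protein-like chains, and is zero for inputs
already on the lattice.

## Energy function

The force field is a weighted sum of five components plus restraints. All
energies and the temperature are dimensionless model quantities.

1. **Local stiffness** — a flat-bottom quadratic penalty on virtual-bond
   angles outside [72°, 150°] (κ = 5 per rad²). Zero for helical and
   typical coil geometry; penalises fully extended (180°) and collapsed
   angles.
2. **Short-range sequence-local terms** — binned statistical potentials
   for the (i, i+2), (i, i+3), (i, i+4) Cα distances, obtained by
   Boltzmann inversion, `−ln((p_obs + ε)/(p_ref + ε))`, of distance
   distributions observed in a reference ensemble against a freely-jointed
   random walk on the same bond-vector set. The shipped defaults are
   derived from lattice-projected ideal helices (a helix-rich derivation
   set), so helical local geometry is the minimum of this term. Entries
   are clipped (±2 in the shipped tables) so rarely observed bins cannot dominate the
   total energy. A single residue-class pair is used; the table structure
   supports finer classes.
3. **Side-chain contacts** — a symmetric 20×20 matrix ranked by
   Kyte–Doolittle hydropathy, `e(a,b) = −1.5·h_a·h_b` with `h` mapped to
   [0, 1]; a pair interacts when the side-chain centers are within
   `4.5 Å + 0.25·(d_a + d_b)` (d = side-chain offsets). The attractive
   part is scaled by mutual side-chain orientation: 1 for antiparallel
   axes, falling linearly in cos to a floor of 0.3 for parallel (clashing)
   ones. Solvent and electrostatics are implicit in this term.
4. **Excluded volume** — hard cores between pseudoatom classes; any
   violation is an infinite-energy (rejected) state, the lattice-MC
   convention that keeps finite energies bounded. Cores are additive in
   per-class radii (Cα 1.5 Å, Cβ 0.7 Å, SC 0.6 Å) with cross-class
   overrides (Cα–Cβ 1.6 Å, Cα–SC 1.2 Å, Cβ–SC 1.2 Å): the deterministic
   outward side-chain construction legitimately brings side-chain centers
   close to neighbouring backbone atoms in compact folds, and additive
   cores would veto valid structures.
5. **Hydrogen bonds** — mid-bond center pairs at sequence separation ≥ 3
   (or on different chains) within 4.0–5.5 Å whose bond vectors are
   sufficiently collinear (|cos| ≥ 0.5) each contribute −1. The i/i+3
   geometry of an α-helix sits inside this window.

**Flat-bottom restraints** hold selected residue pairs near a reference
distance: `k·max(0, |d − d0| − tol)²`. Restraint generation for a
"restrained" segment takes all intra-segment Cα pairs with sequence
separation ≥ 3 and reference distance < 10 Å from the input coordinates
(tol = 1.0 Å, k = 1.0); no restraint ever crosses segments or touches a
fully flexible residue.

### Weight calibration

The relative term weights are not derivable from first principles here;
they were calibrated qualitatively, against three behaviours the model is
designed to show, and are user-editable in `ForceField`:

- an ideal helix is locally stable at the lowest model temperature
  (short-range + hydrogen-bond terms hold helical geometry against
  entropy);
- compact fixtures remain compact (contact attraction balances excluded
  volume);
- a restrained compact domain fluctuates around its starting structure
  with a Cα RMSD in the ~1 Å range at the lowest temperature, the designed
  behaviour of the restraint system.

The flat-bottom tolerance itself sets a hard floor for that last figure:
with tol = 1.0 Å every restrained pair distance can wander ±1 Å at zero
cost, which alone produces ≈ 1 Å of coordinate RMSD in a
distance-restraint network of this density, independent of k. Reported
fluctuation values should be read with that floor in mind.

## Sampling

Conformational sampling is Metropolis Monte Carlo with four local move
types: single-bead jumps (a bead re-placed between its fixed neighbours
using a precomputed two-bond span table), two-bead crankshafts, end-bead
moves, and one-lattice-unit translations of 3–6-residue fragments (default
mix 0.40/0.30/0.15/0.15). A proposal with no valid candidate counts as a
null move. Restrained residues move like free ones — restraints act
through the energy, not through move masking. One MC step is one proposed
elementary move; one sweep is one step per mobile residue.

Replica exchange runs the system at a ladder of temperatures (default 20
replicas, linearly spaced over 1.5–3.4; `n_steps` counts proposals summed
over replicas). Every `exchange_interval` sweeps, adjacent pairs
(alternating even/odd parity per round) attempt a configuration swap with
probability `min(1, exp((1/Ti − 1/Tj)(Ei − Ej)))`; temperatures stay fixed
to replica slots. Each replica owns an independent RNG stream spawned from
the run seed, so identical configurations and seeds reproduce trajectories
bit for bit.

Energies are recomputed from scratch (vectorised) for every proposal
rather than tracked incrementally; at every snapshot the stored total is
re-verified against a fresh evaluation. This trades a constant factor of
speed for bookkeeping that cannot drift, a good bargain at the system
sizes this package targets (≲ 150 residues).

## Docking protocol

1. Parse the receptor (PDB, Cα records suffice), project each chain onto
   the lattice, rebuild pseudoatoms.
2. Build per-segment flexibility: segments marked `restrained` get
   intra-segment flat-bottom restraints from the input geometry; segments
   marked `full_flexible` (e.g. inter-domain linkers) and the peptide get
   none.
3. For each replica, generate the peptide as a random self-avoiding walk
   on the bond-vector set and rigid-place it along a uniformly random
   direction from the receptor's geometric center so that the minimum
   peptide–receptor Cα distance is 20 Å (within one lattice resolution).
   The Cα point cloud is the surface proxy; no molecular-surface algorithm
   is used.
4. Run replica exchange MC; persist the trajectory (compact binary format:
   int16 lattice coordinates per frame, with a multi-model PDB exporter),
   a config echo, and a run log. Runs are split into checkpoint segments
   with per-segment derived seeds, so interrupted runs can resume from the
   last completed segment without changing the full-run result.
5. Post-process: take the second half of each replica's frame sequence
   (frames with index > floor(n/2)), cluster the frames of the selected
   low-temperature replicas (default T = 1.5 and 2.0) by single-linkage
   agglomeration on the pairwise Cα-RMSD matrix cut at 1.5 Å, and report
   per-cluster size, mean energy and the medoid (minimum mean intra-cluster
   RMSD) as the representative.

The flexibility-only mode runs the same engine with no ligand and
whole-chain restraints — fluctuation sampling around the near-native
state, defaulting to a single replica at the lowest temperature.

## Trajectory analysis

- **Superposition/RMSD**: Kabsch (SVD, proper rotation only); degenerate
  inputs (< 3 points or collinear) fall back to translation-only with a
  flag. `RMSDSpec` separates the fitted selection from the measured one,
  expressing the standard docking metrics (whole complex for near-native
  classification at the 6 Å threshold; both receptor domains; the bound
  C-domain + peptide subset) as selections. The fit-and-measure set for
  the bound-subset metric is the union selection; a receptor-only fit is a
  flag away.
- **Transition curve**: per-temperature fraction of frames below the
  near-native threshold (default 6 Å), second half by default; no
  monotonicity assumed.
- **Density maps**: 2D histograms of two per-frame measures (default
  0.5 Å bins), reported both as raw counts and per-cell normalised.
- **Contact profiles**: two residues are in contact when any pair of
  their represented atoms (Cα, Cβ, side-chain center) is closer than
  4.5 Å — the coarse-grained surrogate for an all-atom heavy-atom
  criterion; the profile marks, per peptide residue, contact with any
  residue of a receptor selection.
- **Radius of gyration**: unweighted RMS distance from the centroid.
- **KDE**: `f̂_h(x) = 1/(N·h) Σ K((x − x_i)/h)` with the standard normal
  kernel; the bandwidth defaults to Silverman's rule on the input sample
  and is always echoed in the result.
- **Clustering**: single linkage (complete/average behind a flag) on
  pairwise superposed Cα RMSD, cut at a distance threshold; clusters
  numbered by decreasing size, medoid representatives.

## Synthetic fixtures

All test inputs are generated programmatically:

- **Ideal helices** (rise 1.5 Å, 100°/residue, radius 2.3 Å; bonds
  ≈ 3.83 Å) with amphipathic sequences, in seeded random orientations.
- **Random coils**: self-avoiding 3.8 Å chains with protein-like bond
  angles and a 4.1 Å non-adjacent Cα clearance.
- **Two-domain receptors**: two compact antiparallel two-helix-bundle
  domains joined by an extended flexible linker — the topology of a
  two-lobed calcium-sensor protein bound by a ~30-residue helical peptide.
  Bundle domains (rather than amorphous globules) make the fixture's
  native state a genuine basin of the force field, as for a real folded
  domain, since the local terms are minimised by helical geometry.
  Generators reject candidates whose projected coarse-grained form
  violates excluded volume, so every fixture is a valid sampling start.
- **Planted trajectories**: frames drawn from stated conformer mixtures
  per temperature with optional Gaussian jitter and ground-truth labels —
  the backbone of the analysis test suite, whose statistics (mixture
  weights, cluster structure, transition fractions) must recover the
  generating parameters within binomial bounds.

What the fixtures do **not** emulate: real side-chain chemistry and
rotamers, β structure, sequence-specific folding, or the coordinates of
any real protein; passing tests demonstrate the machinery's
correctness and qualitative behaviour, not biological accuracy on real
complexes.

## Problem sizes and numerical choices

The packaged study conditions use desk-scale sizes chosen as the smallest
systems that exercise every mechanism: 40+6+40-residue receptors,
8–10-residue peptides, 2-replica reduced runs of ~10⁵ proposals for
fluctuation measurements, and ~20-chain ensembles for the casting-error
statistic. The full-scale protocol of the original method (20 replicas,
2×10⁶ steps, ~30-residue peptide) is the library default for production
use. Tolerances: energy bookkeeping is verified to 1e-9 relative at every
snapshot; KDE normalisation to 1e-3 by quadrature; statistical assertions
use 3σ binomial/multinomial bounds (inflated for correlated MC snapshots
by an effective-sample-size factor). Ties in clustering and beam search
are broken deterministically (stable sorts); degenerate geometry
(collinear frames, zero-length side-chain axes) falls back to
deterministic perpendiculars.

## Known limitations

- The statistical potentials are simplified stand-ins derived from
  synthetic fixtures; no claim is made that docking funnels on real
  proteins are reproduced quantitatively.
- The Metropolis scheme is standard (symmetric per-type proposal
  selection); small proposal asymmetries of the crankshaft move are
  neglected.
- The model temperature is dimensionless; mapping to kelvin requires
  calibration at a reference transition and is not provided.
- No all-atom reconstruction of sampled models; exported PDBs contain the
  pseudoatom representation only.
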