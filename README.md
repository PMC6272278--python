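# cgdock

Coarse-grained lattice docking of peptides to flexible multi-domain
receptors, with replica exchange Monte Carlo sampling and a trajectory
analysis suite.

## The problem

Docking a peptide to a receptor whose domains rearrange on binding cannot
be treated as rigid-body search: the receptor's large-scale motions and
the peptide's folding-on-binding have to be sampled together. The classic
system of this kind is a two-lobed calcium-sensor protein whose domains,
joined by a flexible linker, clamp around a ~30-residue helical peptide.
All-atom simulation of such an assembly process is far too slow for a desk
machine; a coarse-grained lattice model is roughly four orders of
magnitude faster and preserves the essential physics.

`cgdock` is aimed at structural-bioinformatics users who want to run and
analyse such simulations end to end: model construction from a Cα-only
PDB, per-segment receptor flexibility (rigid-ish domains, fully flexible
linkers and peptide), sampling, and the standard analysis products
(RMSD subsets, near-native transition curves, conformational density
maps, contact profiles, radius-of-gyration and distance distributions via
kernel density estimation, and RMSD-based clustering with representative
models).

## The model in brief

- Cα atoms live on a cubic lattice (spacing 0.61 Å); consecutive Cα are
  joined by one of exactly 800 admissible integer bond vectors
  (squared-norm window [29, 49], bond lengths 3.28–4.27 Å). Casting a
  protein-like trace onto the lattice costs ≈ 0.3 Å mean coordinate error.
- Each residue additionally carries a Cβ, a side-chain center and
  per-bond hydrogen-bond centers, all deterministic functions of the
  local Cα geometry.
- The energy is a weighted sum of five terms — local backbone stiffness,
  Boltzmann-inverted short-range (i, i+2/3/4) statistical potentials,
  orientation-dependent side-chain contact energies, hard-core excluded
  volume, and mid-bond hydrogen bonds — plus flat-bottom distance
  restraints `k·max(0, |d − d0| − tol)²` that hold restrained segments
  near their input geometry.
- Sampling is Metropolis Monte Carlo (bead jumps, crankshafts, end moves,
  small-fragment translations) replicated over a temperature ladder
  (default 20 replicas, dimensionless T 1.5–3.4) with periodic
  configuration exchange between adjacent temperatures,
  `p = min(1, exp((1/Ti − 1/Tj)(Ei − Ej)))`.
- Docking starts each replica from a random self-avoiding peptide
  conformation placed at a uniformly random direction 20 Å from the
  receptor; analysis uses the second half of the trajectory, clustered by
  single linkage at a 1.5 Å Cα-RMSD cutoff, with 6 Å as the near-native
  threshold and 4.5 Å as the residue contact criterion.

See `docs/methods.md` for the full model description, parameter defaults
and known limitations.

## Worked example

Dock a 10-residue amphipathic peptide to a synthetic two-domain receptor
(40+6+40 residues, domains restrained, linker free). Everything is
generated in code — no downloads:

```python
import numpy as np
import cgdock as cg
from cgdock.docking import (DockingRun, FlexibilityConfig, Segment,
                            run_docking, postprocess, AnalysisConfig)
from cgdock.sampling import ReplicaConfig
from cgdock.analysis import RMSDSpec, transition_curve
from cgdock.fixtures import make_two_domain_receptor

lattice = cg.default_lattice()
coords, seq, ann = make_two_domain_receptor(40, 6, 40, seed=7)
trace, err = cg.project_chain(coords, lattice, chain_id="A")
print(f"receptor: {len(seq)} residues, casting error {err:.2f} A")
receptor = [cg.rebuild_pseudoatoms(trace, seq, lattice)]

(d1s, d1e), (d2s, d2e) = ann["domains"]
flex = FlexibilityConfig([
    Segment("A", d1s + 1, d1e + 1, "restrained"),
    Segment("A", ann["linker"][0] + 1, ann["linker"][1] + 1, "full_flexible"),
    Segment("A", d2s + 1, d2e + 1, "restrained"),
])
config = ReplicaConfig(n_replicas=2, ladder=[1.5, 3.4], t_min=1.5,
                       t_max=3.4, n_steps=40_000, seed=11,
                       exchange_interval=5, snapshot_interval=20)
run = DockingRun(receptor=receptor, ligand_seq="KLLEKLLKLA",
                 flexibility=flex, replica=config, outdir="demo")
result = run_docking(run)
print(f"restraints: {len(result.restraints)}")
print(f"frames: {len(result.trajectory)}")

ref = {"A": receptor[0].ca, "P": result.trajectory.frames[0].coords[1]}
curve = transition_curve(result.trajectory, ref,
                         RMSDSpec("A:1-86;P:1-10", superpose_on="A:1-86"),
                         threshold=6.0)
for T, f, n in zip(curve.temperatures, curve.fractions, curve.counts):
    print(f"T={T:.1f}: near-reference fraction {f:.2f} over {n} frames")
post = postprocess(result.trajectory, AnalysisConfig(cluster_temps=(1.5,)),
                   outdir="demo/post")
res, summaries, frames = post.per_temperature[1.5]
print(f"clusters at T=1.5 (cutoff 1.5 A): {res.n_clusters}; "
      f"largest {res.sizes[0]} frames")
```

Output (a 40 000-proposal toy run; production runs use 20 replicas and
2 000 000 steps):

```
receptor: 86 residues, casting error 0.32 A
restraints: 350
frames: 24
T=1.5: near-reference fraction 1.00 over 6 frames
T=3.4: near-reference fraction 0.00 over 6 frames
clusters at T=1.5 (cutoff 1.5 A): 1; largest 6 frames
```

Reading the numbers: projecting the receptor onto the lattice displaced
each Cα by 0.32 Å on average; 350 flat-bottom restraints cage the two
domains (none touch the linker or the peptide). At the lowest temperature
every second-half frame stays within 6 Å Cα RMSD of the reference pose
(here the starting structure), while the hottest replica has left it —
the temperature dependence the transition curve is designed to expose —
and the low-temperature ensemble collapses into a single structural
cluster whose medoid is exported as the representative model.

The same protocol is available from the shell:

```sh
cgdock fixtures --kind two_domain --n1 40 --linker 6 --n2 40 --seed 7 --out receptor.pdb
cgdock run --receptor receptor.pdb --ligand-seq KLLEKLLKLA \
           --replicas 2 --steps 40000 --seed 11 --out demo/
cgdock cluster --traj demo/trajectory.trj --cutoff 1.5 --temps 1.5 --out demo/post
```

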