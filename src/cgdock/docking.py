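"""Docking and near-native flexibility protocols.

The docking procedure: project the receptor onto the lattice by least
squares, generate the peptide as a random self-avoiding lattice chain,
place it at a uniformly random direction with a minimum peptide–receptor
Cα distance of 20 Å, restrain the receptor segments marked ``restrained``
with intra-segment flat-bottom distance restraints (no cross-segment
restraints; flexible segments and the peptide carry none), then run
replica exchange Monte Carlo and post-process the low-temperature second
half of the trajectory by linkage clustering.

The flexibility-only mode (no ligand) restrains every residue near its
input position and samples fluctuations around the native state.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .lattice import LatticeModel, default_lattice
from .representation import (
    CGChain,
    SystemState,
    read_structure,
    rebuild_pseudoatoms,
)
from .energy import (
    ForceField,
    Restraint,
    RestraintSet,
    default_force_field,
    excluded_volume_energy,
)
from .sampling import ReplicaConfig, Trajectory, run_remc
from . import analysis
from .lattice import LatticeTrace

PLACEMENT_DISTANCE = 20.0  # Å, minimum ligand-receptor Cα distance at start


@dataclass
class Segment:
    """A receptor stretch with one flexibility mode (1-based inclusive)."""

    chain_id: str
    start: int
    end: int
    mode: str  # "full_flexible" | "restrained"

    def __post_init__(self) -> None:
        if self.mode not in ("full_flexible", "restrained"):
            raise ValueError(f"unknown flexibility mode {self.mode!r}")
        if self.start < 1 or self.end < self.start:
            raise ValueError("segment bounds must satisfy 1 <= start <= end")


@dataclass
class FlexibilityConfig:
    """Per-segment receptor flexibility; the ligand is always fully
    flexible.  Segments must cover every receptor residue exactly once."""

    segments: list
    tol: float = 1.0  # Å, flat-bottom half width
    k: float = 1.0  # restraint spring constant
    d0_max: float = 10.0  # Å, only restrain pairs closer than this
    min_sep: int = 3  # minimum sequence separation of restrained pairs

    def validate(self, receptor: list[CGChain]) -> None:
        for chain in receptor:
            covered = np.zeros(len(chain), dtype=int)
            for s in self.segments:
                if s.chain_id != chain.chain_id:
                    continue
                if s.end > len(chain):
                    raise ValueError(
                        f"segment {s.chain_id}:{s.start}-{s.end} exceeds "
                        f"chain length {len(chain)}"
                    )
                covered[s.start - 1:s.end] += 1
            if not np.all(covered == 1):
                bad = int(np.argmin(covered == 1)) + 1
                raise ValueError(
                    f"chain {chain.chain_id!r}: residue {bad} covered "
                    f"{covered[bad - 1]} times (must be exactly once)"
                )
        known = {c.chain_id for c in receptor}
        for s in self.segments:
            if s.chain_id not in known:
                raise ValueError(f"segment references unknown chain "
                                 f"{s.chain_id!r}")

    @classmethod
    def all_restrained(cls, receptor: list[CGChain], **kw) -> "FlexibilityConfig":
        return cls(
            [Segment(c.chain_id, 1, len(c), "restrained") for c in receptor], **kw
        )

    @classmethod
    def all_flexible(cls, receptor: list[CGChain]) -> "FlexibilityConfig":
        return cls(
            [Segment(c.chain_id, 1, len(c), "full_flexible") for c in receptor]
        )


def make_restraints(
    receptor: list[CGChain], flexibility: FlexibilityConfig
) -> RestraintSet:
    """Flat-bottom restraints between all Cα pairs inside each restrained
    segment (sequence separation >= min_sep, reference distance < d0_max,
    taken from the current coordinates).  Never across segments, never
    touching a fully flexible residue."""
    flexibility.validate(receptor)
    by_id = {c.chain_id: c for c in receptor}
    restraints = []
    for s in flexibility.segments:
        if s.mode != "restrained":
            continue
        chain = by_id[s.chain_id]
        idx = np.arange(s.start - 1, s.end)
        ca = chain.ca[idx]
        n = len(idx)
        for a in range(n):
            for b in range(a + flexibility.min_sep, n):
                d0 = float(np.linalg.norm(ca[a] - ca[b]))
                if d0 < flexibility.d0_max:
                    restraints.append(
                        Restraint(s.chain_id, int(idx[a]), s.chain_id,
                                  int(idx[b]), d0, flexibility.tol,
                                  flexibility.k)
                    )
        chain.flexibility[idx] = True
    return RestraintSet(restraints)


# ---------------------------------------------------------------------------
# system construction
# ---------------------------------------------------------------------------


def _random_lattice_chain(
    n_res: int, lattice: LatticeModel, rng: np.random.Generator,
    max_tries: int = 2000,
) -> np.ndarray:
    """Self-avoiding random walk on the bond-vector set (lattice units)."""
    vecs = lattice.vectors
    for _ in range(50):
        pts = [np.zeros(3, dtype=np.int64)]
        ok = True
        for _i in range(1, n_res):
            placed = False
            for _t in range(max_tries // n_res + 10):
                cand = pts[-1] + vecs[int(rng.integers(len(vecs)))]
                if len(pts) > 1:
                    d2 = ((np.array(pts[:-1]) - cand) ** 2).sum(axis=1)
                    if (d2 < lattice.min_sep2).any():
                        continue
                pts.append(cand)
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            return np.array(pts)
    raise RuntimeError("could not grow a random lattice chain")


def build_docking_system(
    receptor: list[CGChain],
    ligand_sequence: str,
    lattice: LatticeModel,
    rng: np.random.Generator,
    ff: ForceField | None = None,
    placement_distance: float = PLACEMENT_DISTANCE,
    ligand_chain_id: str = "P",
    max_tries: int = 50,
) -> SystemState:
    """One replica's starting state: the projected receptor plus a random
    peptide conformation rigid-placed along a uniformly random direction
    from the receptor's geometric center so that the minimum peptide–
    receptor Cα distance is ``placement_distance`` (within one lattice
    resolution)."""
    if len(ligand_sequence) < 3:
        raise ValueError("ligand must have at least 3 residues")
    ff = ff or default_force_field()
    a = lattice.constant
    rec_ca = np.vstack([c.ca for c in receptor])
    center = rec_ca.mean(axis=0)
    tol = a  # ±1 lattice resolution around the target distance

    for _ in range(max_tries):
        conf = _random_lattice_chain(len(ligand_sequence), lattice, rng)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        lig_centroid = conf.mean(axis=0) * a
        r_max = np.linalg.norm(rec_ca - center, axis=1).max()
        lig_r = np.linalg.norm(conf * a - lig_centroid, axis=1).max()
        t_lo = 0.0
        t_hi = r_max + lig_r + placement_distance + 5 * a
        placed = None
        for t in np.arange(t_lo, t_hi, a / 4):
            target = center + direction * t
            offset = np.round((target - lig_centroid) / a).astype(np.int64)
            lig_ca = (conf + offset) * a
            dmin = float(np.min(
                np.linalg.norm(rec_ca[:, None, :] - lig_ca[None, :, :], axis=2)
            ))
            if abs(dmin - placement_distance) <= tol:
                placed = conf + offset
                break
            if dmin > placement_distance + tol:
                break
        if placed is None:
            continue
        trace = LatticeTrace(placed, ligand_chain_id)
        ligand = rebuild_pseudoatoms(trace, ligand_sequence, lattice)
        state = SystemState(receptor=[c.copy() for c in receptor], ligand=ligand)
        if excluded_volume_energy(state, ff) == 0.0:
            return state
    raise RuntimeError("ligand placement failed after bounded retries")


# ---------------------------------------------------------------------------
# run orchestration
# ---------------------------------------------------------------------------


@dataclass
class AnalysisConfig:
    cluster_cutoff: float = 1.5  # Å, linkage clustering cutoff
    cluster_temps: tuple = (1.5, 2.0)  # replicas whose models are clustered
    near_native_threshold: float = 6.0  # Å
    linkage_method: str = "single"


@dataclass
class DockingRun:
    """Everything needed to execute and persist one docking simulation."""

    receptor: object  # path to PDB, or list[CGChain]
    ligand_seq: str | None
    flexibility: FlexibilityConfig | None = None
    replica: ReplicaConfig = field(default_factory=ReplicaConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    outdir: str | None = None
    checkpoint_segments: int = 4


@dataclass
class DockingResult:
    trajectory: Trajectory
    ensembles: list
    restraints: RestraintSet
    receptor: list
    outdir: str | None = None


def _load_receptor(source, lattice) -> list[CGChain]:
    if isinstance(source, (str, Path)):
        chains, _ = read_structure(source, lattice=lattice)
        return chains
    return [c.copy() for c in source]


def _echo_config(run: DockingRun, path: Path) -> None:
    cfg = {
        "ligand_seq": run.ligand_seq,
        "replica": {k: v for k, v in asdict(run.replica).items()},
        "analysis": asdict(run.analysis),
        "flexibility": None
        if run.flexibility is None
        else {
            "segments": [asdict(s) for s in run.flexibility.segments],
            "tol": run.flexibility.tol,
            "k": run.flexibility.k,
            "d0_max": run.flexibility.d0_max,
        },
        "checkpoint_segments": run.checkpoint_segments,
    }
    path.write_text(json.dumps(cfg, indent=2, default=str))


def run_docking(
    run: DockingRun,
    ff: ForceField | None = None,
    lattice: LatticeModel | None = None,
    resume: bool = False,
) -> DockingResult:
    """Execute build → restraints → replica exchange → persistence.

    The run is split into ``checkpoint_segments`` equal slices of the step
    budget; replica states are checkpointed after each slice, and
    ``resume=True`` continues from the last completed slice.  Identical
    config and seed reproduce the trajectory bit for bit (resumed or not,
    the per-slice RNG streams are derived the same way).
    """
    lattice = lattice or default_lattice()
    ff = ff or default_force_field()
    outdir = Path(run.outdir) if run.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    receptor = _load_receptor(run.receptor, lattice)
    if run.ligand_seq is None:
        return _run_flex_impl(receptor, run, ff, lattice)

    flexibility = run.flexibility or FlexibilityConfig.all_restrained(receptor)
    restraints = make_restraints(receptor, flexibility)

    cfg = run.replica
    ss = np.random.SeedSequence(cfg.seed)
    build_rngs = [np.random.default_rng(c) for c in ss.spawn(cfg.n_replicas)]
    states = [
        build_docking_system(receptor, run.ligand_seq, lattice, build_rngs[r], ff)
        for r in range(cfg.n_replicas)
    ]

    n_seg = max(1, run.checkpoint_segments)
    seg_steps = [cfg.n_steps // n_seg] * n_seg
    seg_steps[-1] += cfg.n_steps - sum(seg_steps)
    seg_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2 * n_seg)[n_seg:]]

    start_seg = 0
    if resume and outdir and (outdir / "checkpoint.npz").exists():
        states, start_seg = _load_checkpoint(outdir / "checkpoint.npz", states,
                                             lattice)

    traj = Trajectory(
        chain_meta=[(c.chain_id, c.sequence) for c in states[0].chains],
        lattice_constant=lattice.constant,
    )
    ensembles = []
    log_lines = []
    step_offset = sum(seg_steps[:start_seg]) // cfg.n_replicas
    t0 = time.time()
    for seg in range(start_seg, n_seg):
        seg_cfg = ReplicaConfig(
            n_replicas=cfg.n_replicas, t_min=cfg.t_min, t_max=cfg.t_max,
            ladder=list(cfg.ladder), exchange_interval=cfg.exchange_interval,
            n_steps=seg_steps[seg], seed=seg_seeds[seg],
            snapshot_interval=cfg.snapshot_interval,
            move_weights=dict(cfg.move_weights),
        )
        seg_traj, ens = run_remc(states, ff, restraints, seg_cfg, lattice)
        frames = seg_traj.frames if seg == start_seg else [
            f for f in seg_traj.frames if f.step > 0
        ]
        for f in frames:
            f.step += step_offset
        traj.frames.extend(frames)
        step_offset += seg_steps[seg] // cfg.n_replicas
        states = ens.states
        ensembles.append(ens)
        if outdir:
            _save_checkpoint(outdir / "checkpoint.npz", states, seg + 1)
        acc = {
            k: (v[1] / v[0] if v[0] else 0.0) for k, v in ens.move_stats.items()
        }
        log_lines.append(
            f"segment {seg + 1}/{n_seg}: move acceptance {acc}; "
            f"exchange {dict(ens.exchange_stats)}; "
            f"elapsed {time.time() - t0:.1f}s"
        )

    if outdir:
        traj.write(outdir / "trajectory.trj")
        _echo_config(run, outdir / "config.json")
        (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return DockingResult(traj, ensembles, restraints, receptor,
                         str(outdir) if outdir else None)


def _save_checkpoint(path: Path, states, segment: int) -> None:
    arrays = {"segment": np.array([segment])}
    for r, st in enumerate(states):
        for k, c in enumerate(st.chains):
            arrays[f"r{r}c{k}"] = c.trace.positions
    np.savez(path, **arrays)


def _load_checkpoint(path: Path, states, lattice):
    data = np.load(path)
    segment = int(data["segment"][0])
    for r, st in enumerate(states):
        for k, c in enumerate(st.chains):
            c.trace.positions = data[f"r{r}c{k}"].astype(np.int64)
            c.refresh(lattice)
    return states, segment


# ---------------------------------------------------------------------------
# flexibility-only mode
# ---------------------------------------------------------------------------


def _run_flex_impl(receptor, run: DockingRun, ff, lattice) -> DockingResult:
    flexibility = run.flexibility or FlexibilityConfig.all_restrained(receptor)
    restraints = make_restraints(receptor, flexibility)
    states = [
        SystemState(receptor=[c.copy() for c in receptor])
        for _ in range(run.replica.n_replicas)
    ]
    traj, ens = run_remc(states, ff, restraints, run.replica, lattice)
    outdir = Path(run.outdir) if run.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
        traj.write(outdir / "trajectory.trj")
        _echo_config(run, outdir / "config.json")
    return DockingResult(traj, [ens], restraints, receptor,
                         str(outdir) if outdir else None)


def run_flex(
    structure,
    config: ReplicaConfig | None = None,
    flexibility: FlexibilityConfig | None = None,
    ff: ForceField | None = None,
    lattice: LatticeModel | None = None,
    outdir: str | None = None,
) -> DockingResult:
    """Near-native fluctuation sampling: all residues restrained to their
    input geometry (whole-chain restraint generation, same filters as
    docking), no ligand.  Defaults to a single replica at the lowest model
    temperature; the second half of the trajectory is the analysis set."""
    lattice = lattice or default_lattice()
    ff = ff or default_force_field()
    if config is None:
        config = ReplicaConfig(n_replicas=1, ladder=[1.5], n_steps=50_000)
    run = DockingRun(
        receptor=structure, ligand_seq=None, flexibility=flexibility,
        replica=config, outdir=outdir,
    )
    receptor = _load_receptor(structure, lattice)
    return _run_flex_impl(receptor, run, ff, lattice)


# ---------------------------------------------------------------------------
# post-processing
# ---------------------------------------------------------------------------


@dataclass
class ClusterSummary:
    cluster_id: int
    size: int
    representative_frame: int  # index into the selected frame list
    mean_energy: float


@dataclass
class PostprocessResult:
    per_temperature: dict  # T -> (ClusterResult, [ClusterSummary], frames)

    def table(self):
        import pandas as pd

        rows = []
        for t, (res, summaries, _) in self.per_temperature.items():
            for s in summaries:
                rows.append(
                    {"temperature": t, "cluster": s.cluster_id,
                     "size": s.size,
                     "representative_frame": s.representative_frame,
                     "mean_energy": s.mean_energy}
                )
        return pd.DataFrame(rows)


def postprocess(
    traj: Trajectory,
    config: AnalysisConfig | None = None,
    outdir: str | None = None,
) -> PostprocessResult:
    """Cluster the second-half frames of the selected temperature replicas
    (linkage method at the configured cutoff) and export cluster tables and
    medoid representatives."""
    config = config or AnalysisConfig()
    out = {}
    for t in config.cluster_temps:
        frames = traj.select(temperature=t, second_half=True)
        if len(frames) < 2:
            raise ValueError(f"no frames to cluster at T={t}")
        res = analysis.cluster_frames(
            frames, cutoff=config.cluster_cutoff, method=config.linkage_method
        )
        summaries = []
        for c in range(res.n_clusters):
            members = np.nonzero(res.labels == c)[0]
            summaries.append(
                ClusterSummary(
                    cluster_id=c,
                    size=int(res.sizes[c]),
                    representative_frame=int(res.medoids[c]),
                    mean_energy=float(
                        np.mean([frames[i].energy for i in members])
                    ),
                )
            )
        out[t] = (res, summaries, frames)
    result = PostprocessResult(out)
    if outdir:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        result.table().to_csv(outdir / "clusters.tsv", sep="\t", index=False)
        for t, (res, summaries, frames) in out.items():
            reps = [frames[s.representative_frame] for s in summaries]
            traj.to_pdb(outdir / f"representatives_T{t}.pdb", reps)
    return result
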