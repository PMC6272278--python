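"""Replica exchange Monte Carlo on the lattice.

Local move set (single-bead jump, two-bead crankshaft, end-bead move,
3-6-residue fragment translation) under the Metropolis criterion, replicated
across a temperature ladder with periodic configuration exchange between
adjacent temperatures.  Temperatures stay fixed to replica slots; only
configurations migrate.  The model temperature is dimensionless.

One MC step is one proposed elementary move; one sweep is one step per
mobile residue.  ``n_steps`` counts proposals summed over all replicas
(rounded down to a multiple of the replica count).
"""

from __future__ import annotations

import math
import struct
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .lattice import LatticeModel, LatticeTrace, default_lattice
from .representation import CGChain, SystemState, write_structure
from .energy import ForceField, RestraintSet, total_energy

DEFAULT_MOVE_WEIGHTS = {
    "bead_jump": 0.4,
    "crankshaft": 0.3,
    "end": 0.15,
    "fragment": 0.15,
}

_UNIT_SHIFTS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
    dtype=np.int64,
)


@dataclass
class ReplicaConfig:
    """Settings for a replica exchange run."""

    n_replicas: int = 20
    t_min: float = 1.5
    t_max: float = 3.4
    ladder: Sequence[float] | None = None
    exchange_interval: int = 10  # sweeps between exchange rounds
    n_steps: int = 2_000_000  # proposals summed over replicas
    seed: int = 0
    snapshot_interval: int = 100  # sweeps between saved frames
    move_weights: dict | None = None

    def __post_init__(self) -> None:
        if self.ladder is None:
            if self.n_replicas == 1:
                self.ladder = [self.t_min]
            else:
                self.ladder = list(
                    np.linspace(self.t_min, self.t_max, self.n_replicas)
                )
        self.ladder = [float(t) for t in self.ladder]
        if len(self.ladder) != self.n_replicas:
            raise ValueError("ladder length must equal n_replicas")
        if any(b <= a for a, b in zip(self.ladder, self.ladder[1:])):
            raise ValueError("temperature ladder must be strictly increasing")
        if self.ladder[0] < self.t_min - 1e-12 or self.ladder[-1] > self.t_max + 1e-12:
            raise ValueError("ladder must lie within [t_min, t_max]")
        if self.exchange_interval < 1 or self.snapshot_interval < 1:
            raise ValueError("intervals must be >= 1")
        if self.n_steps < 0:
            raise ValueError("n_steps must be non-negative")
        if self.move_weights is None:
            self.move_weights = dict(DEFAULT_MOVE_WEIGHTS)


@dataclass
class Frame:
    """One saved trajectory frame (coordinates in Å)."""

    replica: int
    temperature: float
    step: int
    coords: list  # per chain, (n, 3) float Å
    energy: float
    terms: dict = field(default_factory=dict)
    latt: list | None = None  # per chain, (n, 3) int lattice positions
    label: int = -1  # ground-truth conformer id for planted fixtures


@dataclass
class Trajectory:
    """Ordered frames with chain metadata; input to all analysis operations."""

    chain_meta: list  # (chain_id, sequence) per chain
    frames: list = field(default_factory=list)
    lattice_constant: float = 0.0

    def __len__(self) -> int:
        return len(self.frames)

    def select(
        self,
        temperature: float | None = None,
        second_half: bool = False,
        replica: int | None = None,
    ) -> list[Frame]:
        """Filter frames; ``second_half`` keeps frames with index >
        floor(n/2) within each replica's own frame sequence."""
        frames = self.frames
        if replica is not None:
            frames = [f for f in frames if f.replica == replica]
        if temperature is not None:
            frames = [f for f in frames if abs(f.temperature - temperature) < 1e-9]
        if second_half:
            by_rep: dict[int, list[Frame]] = {}
            for f in frames:
                by_rep.setdefault(f.replica, []).append(f)
            frames = [f for fs in by_rep.values() for f in fs[len(fs) // 2:]]
            frames.sort(key=lambda f: (f.step, f.replica))
        return frames

    # -- compact binary format ---------------------------------------------
    # header: magic "CGTRJ1", coord dtype flag, lattice constant, chain table
    # frame:  step, replica, temperature, energy, label, coordinates
    #         (int16 lattice units when available, else float32 Å)

    def write(self, path) -> None:
        on_lattice = all(f.latt is not None for f in self.frames) and self.frames
        with open(path, "wb") as fh:
            fh.write(b"CGTRJ1")
            fh.write(struct.pack("<Bd", 1 if on_lattice else 0,
                                 self.lattice_constant))
            fh.write(struct.pack("<H", len(self.chain_meta)))
            for cid, seq in self.chain_meta:
                cid_b, seq_b = cid.encode(), seq.encode()
                fh.write(struct.pack("<H", len(cid_b)) + cid_b)
                fh.write(struct.pack("<H", len(seq_b)) + seq_b)
            fh.write(struct.pack("<q", len(self.frames)))
            for f in self.frames:
                fh.write(struct.pack("<qid d i", f.step, f.replica,
                                     f.temperature, f.energy, f.label))
                for k in range(len(self.chain_meta)):
                    if on_lattice:
                        fh.write(np.asarray(f.latt[k], dtype="<i2").tobytes())
                    else:
                        fh.write(np.asarray(f.coords[k], dtype="<f4").tobytes())

    @classmethod
    def read(cls, path) -> "Trajectory":
        with open(path, "rb") as fh:
            if fh.read(6) != b"CGTRJ1":
                raise ValueError("not a compact trajectory file")
            on_lattice, const = struct.unpack("<Bd", fh.read(9))
            (n_chains,) = struct.unpack("<H", fh.read(2))
            meta = []
            for _ in range(n_chains):
                (lc,) = struct.unpack("<H", fh.read(2))
                cid = fh.read(lc).decode()
                (ls,) = struct.unpack("<H", fh.read(2))
                seq = fh.read(ls).decode()
                meta.append((cid, seq))
            (n_frames,) = struct.unpack("<q", fh.read(8))
            traj = cls(chain_meta=meta, lattice_constant=const)
            for _ in range(n_frames):
                step, rep, temp, energy, label = struct.unpack(
                    "<qid d i", fh.read(struct.calcsize("<qid d i"))
                )
                coords, latt = [], []
                for cid, seq in meta:
                    n = len(seq)
                    if on_lattice:
                        pos = np.frombuffer(fh.read(n * 3 * 2), dtype="<i2")
                        pos = pos.reshape(n, 3).astype(np.int64)
                        latt.append(pos)
                        coords.append(pos.astype(float) * const)
                    else:
                        xyz = np.frombuffer(fh.read(n * 3 * 4), dtype="<f4")
                        coords.append(xyz.reshape(n, 3).astype(float))
                traj.frames.append(
                    Frame(replica=rep, temperature=temp, step=step,
                          coords=coords, energy=energy,
                          latt=latt if on_lattice else None, label=label)
                )
            return traj

    def to_pdb(self, path, frames: list[Frame] | None = None) -> None:
        """Export frames as a multi-model PDB."""
        frames = self.frames if frames is None else frames
        models = []
        for f in frames:
            chains = []
            for (cid, seq), xyz in zip(self.chain_meta, f.coords):
                from .representation import pseudoatoms_from_ca

                cb, sc, hb = pseudoatoms_from_ca(xyz, seq)
                trace = LatticeTrace(np.zeros((len(seq), 3), dtype=np.int64), cid)
                chains.append(CGChain(sequence=seq, trace=trace, ca=xyz,
                                      cb=cb, sc=sc, hb_center=hb))
            models.append(chains)
        write_structure(models, path, multi_model=True)


@dataclass
class ReplicaEnsemble:
    """The simultaneous system states at the temperature ladder."""

    states: list  # per-replica SystemState
    temperatures: list
    rngs: list
    exchange_rng: np.random.Generator
    exchange_stats: dict = field(default_factory=dict)  # (i, i+1) -> [att, acc]
    move_stats: dict = field(default_factory=dict)  # kind -> [att, acc]


# ---------------------------------------------------------------------------
# elementary moves
# ---------------------------------------------------------------------------


@dataclass
class Move:
    kind: str
    chain_index: int
    start: int  # first residue whose position changes
    new_positions: np.ndarray  # (m, 3) int


def propose_move(
    state: SystemState,
    lattice: LatticeModel,
    rng: np.random.Generator,
    weights: dict | None = None,
) -> tuple[str, Move | None]:
    """Draw a move type from the configured weights and attempt it.

    Returns (kind, move); move is None when no valid candidate exists for
    the drawn type (a null move, still counted).  Restrained residues move
    like free ones: restraints act through the energy, not move masking.
    """
    weights = weights or DEFAULT_MOVE_WEIGHTS
    chains = state.chains
    lens = np.array([len(c) for c in chains], dtype=float)
    ci = int(rng.choice(len(chains), p=lens / lens.sum()))
    P = chains[ci].trace.positions
    n = len(P)
    kinds = list(weights)
    probs = np.array([weights[k] for k in kinds], dtype=float)
    kind = kinds[int(rng.choice(len(kinds), p=probs / probs.sum()))]
    vecs = lattice.vectors
    table = lattice.two_bond_table

    if kind == "bead_jump":
        if n < 3:
            return kind, None
        i = int(rng.integers(1, n - 1))
        span = tuple(int(x) for x in (P[i + 1] - P[i - 1]))
        cands = table.get(span)
        if cands is None or len(cands) == 0:
            return kind, None
        v = vecs[cands[int(rng.integers(len(cands)))]]
        return kind, Move(kind, ci, i, (P[i - 1] + v)[None, :])

    if kind == "crankshaft":
        if n < 4:
            return kind, None
        i = int(rng.integers(1, n - 2))
        q_i = P[i - 1] + vecs[int(rng.integers(len(vecs)))]
        span = tuple(int(x) for x in (P[i + 2] - q_i))
        cands = table.get(span)
        if cands is None or len(cands) == 0:
            return kind, None
        q_j = q_i + vecs[cands[int(rng.integers(len(cands)))]]
        return kind, Move(kind, ci, i, np.stack([q_i, q_j]))

    if kind == "end":
        if n < 2:
            return kind, None
        v = vecs[int(rng.integers(len(vecs)))]
        if rng.integers(2) == 0:
            return kind, Move(kind, ci, 0, (P[1] + v)[None, :])
        return kind, Move(kind, ci, n - 1, (P[n - 2] + v)[None, :])

    if kind == "fragment":
        if n < 3:
            return kind, None
        L = int(rng.integers(3, min(6, n) + 1))
        s = int(rng.integers(0, n - L + 1))
        shift = _UNIT_SHIFTS[int(rng.integers(6))]
        if s > 0 and not lattice.is_bond(P[s] + shift - P[s - 1]):
            return kind, None
        if s + L < n and not lattice.is_bond(P[s + L] - (P[s + L - 1] + shift)):
            return kind, None
        return kind, Move(kind, ci, s, P[s:s + L] + shift)

    raise ValueError(f"unknown move kind {kind!r}")


def metropolis_accept(
    delta_e: float, temperature: float, rng: np.random.Generator
) -> bool:
    """Accept with probability min(1, exp(-ΔE / T))."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if delta_e <= 0:
        return True
    if math.isinf(delta_e):
        return False
    return rng.random() < math.exp(-delta_e / temperature)


def attempt_exchange(
    ensemble: ReplicaEnsemble, pair: tuple[int, int], rng: np.random.Generator
) -> bool:
    """Swap configurations of adjacent replicas with probability
    min(1, exp((1/Ti - 1/Tj)(Ei - Ej))); temperatures stay in their slots."""
    i, j = pair
    if j != i + 1:
        raise ValueError("exchange pair must be adjacent in the ladder")
    ti, tj = ensemble.temperatures[i], ensemble.temperatures[j]
    ei = ensemble.states[i].total_energy
    ej = ensemble.states[j].total_energy
    stats = ensemble.exchange_stats.setdefault((i, j), [0, 0])
    stats[0] += 1
    ln_p = (1.0 / ti - 1.0 / tj) * (ei - ej)
    accept = ln_p >= 0 or rng.random() < math.exp(ln_p)
    if accept:
        ensemble.states[i], ensemble.states[j] = (
            ensemble.states[j],
            ensemble.states[i],
        )
        stats[1] += 1
    return accept


# ---------------------------------------------------------------------------
# the REMC driver
# ---------------------------------------------------------------------------


def _default_energy_fn(ff: ForceField, restraints: RestraintSet | None) -> Callable:
    def fn(state: SystemState):
        return total_energy(state, ff, restraints)

    return fn


def _apply_move(state: SystemState, move: Move, lattice: LatticeModel):
    chain = state.chains[move.chain_index]
    saved = (
        chain.trace.positions.copy(),
        chain.ca, chain.cb, chain.sc, chain.hb_center,
    )
    m = len(move.new_positions)
    chain.trace.positions[move.start:move.start + m] = move.new_positions
    chain.refresh(lattice)
    return saved


def _revert_move(state: SystemState, move: Move, saved) -> None:
    chain = state.chains[move.chain_index]
    chain.trace.positions = saved[0]
    chain.ca, chain.cb, chain.sc, chain.hb_center = saved[1:]


def run_remc(
    builder,
    ff: ForceField | None,
    restraints: RestraintSet | None,
    config: ReplicaConfig,
    lattice: LatticeModel | None = None,
    energy_fn: Callable | None = None,
) -> tuple[Trajectory, ReplicaEnsemble]:
    """Run replica exchange Monte Carlo.

    ``builder`` is either a list of per-replica SystemStates or a callable
    ``(replica_index, rng) -> SystemState`` (the docking protocol supplies
    distinct ligand starts this way).  Identical configs and seeds give
    bit-identical trajectories.
    """
    lattice = lattice or default_lattice()
    energy_fn = energy_fn or _default_energy_fn(ff, restraints)
    ladder = list(config.ladder)
    n_rep = config.n_replicas

    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(n_rep + 1)
    rngs = [np.random.default_rng(c) for c in children[:n_rep]]
    exchange_rng = np.random.default_rng(children[n_rep])

    if callable(builder):
        states = [builder(r, rngs[r]) for r in range(n_rep)]
    else:
        states = [s for s in builder]
    if len(states) != n_rep:
        raise ValueError("need one initial state per replica")
    for r, st in enumerate(states):
        e, terms = energy_fn(st)
        if math.isinf(e):
            raise ValueError(
                f"replica {r}: initial state violates excluded volume"
            )
        st.total_energy, st.energy_terms = e, terms

    ensemble = ReplicaEnsemble(
        states=states, temperatures=ladder, rngs=rngs, exchange_rng=exchange_rng
    )
    for k in config.move_weights:
        ensemble.move_stats.setdefault(k, [0, 0])

    meta = [(c.chain_id, c.sequence) for c in states[0].chains]
    traj = Trajectory(chain_meta=meta, lattice_constant=lattice.constant)

    def snapshot(r: int, step: int) -> None:
        st = ensemble.states[r]
        e, terms = energy_fn(st)  # from-scratch consistency check
        if not math.isclose(e, st.total_energy, rel_tol=1e-9, abs_tol=1e-9):
            raise AssertionError(
                f"energy bookkeeping drifted: {st.total_energy} vs {e}"
            )
        traj.frames.append(
            Frame(
                replica=r,
                temperature=ladder[r],
                step=step,
                coords=[c.ca.copy() for c in st.chains],
                energy=e,
                terms=dict(terms),
                latt=[c.trace.positions.copy() for c in st.chains],
            )
        )

    n_mobile = sum(len(c) for c in states[0].chains)
    sweep_len = max(n_mobile, 1)
    steps_per_replica = config.n_steps // n_rep
    total_sweeps = -(-steps_per_replica // sweep_len)  # ceil

    for r in range(n_rep):
        snapshot(r, 0)

    done = [0] * n_rep
    for sweep in range(1, total_sweeps + 1):
        for r in range(n_rep):
            rng = rngs[r]
            T = ladder[r]
            k = min(sweep_len, steps_per_replica - done[r])
            for _ in range(k):
                kind, move = propose_move(
                    ensemble.states[r], lattice, rng, config.move_weights
                )
                ensemble.move_stats[kind][0] += 1
                if move is None:
                    continue
                st = ensemble.states[r]
                saved = _apply_move(st, move, lattice)
                e_new, terms = energy_fn(st)
                if metropolis_accept(e_new - st.total_energy, T, rng):
                    st.total_energy, st.energy_terms = e_new, terms
                    ensemble.move_stats[kind][1] += 1
                else:
                    _revert_move(st, move, saved)
            done[r] += k
        if n_rep > 1 and sweep % config.exchange_interval == 0:
            parity = (sweep // config.exchange_interval) % 2
            for i in range(parity, n_rep - 1, 2):
                attempt_exchange(ensemble, (i, i + 1), exchange_rng)
        if sweep % config.snapshot_interval == 0 or sweep == total_sweeps:
            for r in range(n_rep):
                snapshot(r, done[r])

    return traj, ensemble
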