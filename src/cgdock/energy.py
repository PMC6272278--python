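"""Force field for the coarse-grained lattice model.

Five components plus restraints:

1. sequence-independent local stiffness — a flat-bottom penalty on virtual
   Cα bond angles that leave the protein-like band;
2. sequence-dependent short-range terms — binned statistical potentials for
   the (i, i+2), (i, i+3) and (i, i+4) Cα distances, obtained by Boltzmann
   inversion of observed distributions against a freely-jointed reference
   walk on the same bond-vector set;
3. side-chain–side-chain contact energies from a 20x20 matrix, with the
   attractive part scaled by the mutual orientation of the side-chain axes;
4. hard-core excluded volume between pseudoatom classes (infinite energy,
   i.e. move rejection);
5. hydrogen bonds between mid-bond centers under distance and collinearity
   cutoffs.

Solvent and electrostatics are implicit in the contact matrix.  All energies
and the temperature are dimensionless model quantities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy.spatial.distance import cdist

from .lattice import CA_CA_HARDCORE
from .representation import CGChain, SC_DISTANCE, SystemState

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Kyte-Doolittle hydropathy, used to rank the shipped contact matrix.
_KD = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8,
    "G": -0.4, "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8,
    "M": 1.9, "N": -3.5, "P": -1.6, "Q": -3.5, "R": -4.5,
    "S": -0.8, "T": -0.7, "V": 4.2, "W": -0.9, "Y": -1.3,
}

INF = math.inf


def default_contact_matrix(scale: float = 1.5) -> np.ndarray:
    """Hydrophobicity-ranked 20x20 contact matrix, e(a,b) = -scale·h_a·h_b
    with h the hydropathy mapped to [0, 1].  Symmetric, attractive, strongest
    between hydrophobic pairs."""
    h = np.array([( _KD[a] + 4.5) / 9.0 for a in AMINO_ACIDS])
    return -scale * np.outer(h, h)


def residue_class(aa: str) -> str:
    """Residue class used to index the short-range tables (single class)."""
    return "X"


@dataclass
class ShortRangeTables:
    """Binned (i, i+k) Cα-distance potentials, k in {2, 3, 4}."""

    bin_edges: np.ndarray
    tables: dict  # (k, (class_a, class_b)) -> np.ndarray over bins

    def lookup(self, k: int, cls: tuple[str, str]) -> np.ndarray:
        key = (k, cls)
        if key not in self.tables:
            key = (k, ("X", "X"))
        return self.tables[key]


def boltzmann_invert(
    p_obs: np.ndarray,
    p_ref: np.ndarray,
    pseudocount: float = 1e-4,
    cap: float | None = 3.0,
) -> np.ndarray:
    """-ln((observed + pc) / (reference + pc)) per bin, optionally clipped.

    Identical distributions give exactly zero; a bin observed at twice the
    reference frequency approaches -ln 2 as the pseudocount vanishes.
    """
    p_obs = np.asarray(p_obs, dtype=float)
    p_ref = np.asarray(p_ref, dtype=float)
    tab = -np.log((p_obs + pseudocount) / (p_ref + pseudocount))
    if cap is not None:
        tab = np.clip(tab, -cap, cap)
    return tab


def derive_short_range_tables(
    reference_traces: Iterable[np.ndarray],
    bin_edges: np.ndarray | None = None,
    pseudocount: float = 1e-4,
    n_reference_samples: int = 200_000,
    seed: int = 12345,
    cap: float | None = 3.0,
    lattice=None,
) -> ShortRangeTables:
    """Boltzmann inversion of (i, i+k) distance statistics.

    table[k, bin] = -ln((observed + pc) / (reference + pc)) with both
    distributions normalised; the reference is a freely-jointed random walk
    on the lattice bond-vector set (seeded sampling, deterministic).
    ``cap`` clips the inverted potential to ±cap so that rarely observed
    bins cannot dominate the total energy (None disables clipping).
    """
    traces = [np.asarray(t, dtype=float) for t in reference_traces]
    if not traces:
        raise ValueError("need at least one reference trace")
    if bin_edges is None:
        bin_edges = np.arange(2.0, 18.0 + 1e-9, 0.5)
    bin_edges = np.asarray(bin_edges, dtype=float)
    if not np.all(np.diff(bin_edges) > 0):
        raise ValueError("bin edges must be strictly increasing")

    from .lattice import default_lattice

    lattice = lattice or default_lattice()
    rng = np.random.default_rng(seed)
    vecs = lattice.vectors.astype(float) * lattice.constant

    tables = {}
    for k in (2, 3, 4):
        obs = np.concatenate(
            [
                np.linalg.norm(t[k:] - t[:-k], axis=1)
                for t in traces
                if len(t) > k
            ]
        )
        idx = rng.integers(0, len(vecs), size=(n_reference_samples, k))
        ref = np.linalg.norm(vecs[idx].sum(axis=1), axis=1)
        h_obs, _ = np.histogram(obs, bins=bin_edges)
        h_ref, _ = np.histogram(ref, bins=bin_edges)
        p_obs = h_obs / max(h_obs.sum(), 1)
        p_ref = h_ref / max(h_ref.sum(), 1)
        tables[(k, ("X", "X"))] = boltzmann_invert(p_obs, p_ref, pseudocount, cap)
    return ShortRangeTables(bin_edges=bin_edges, tables=tables)


@dataclass
class ForceField:
    """Term weights and parameter tables for the energy components."""

    # weights calibrated qualitatively: helix stability at the lowest model
    # temperature, compactness, ~1 Å restrained-domain fluctuations
    w_local: float = 1.0
    w_short: float = 1.0
    w_contact: float = 1.0
    w_excluded: float = 1.0
    w_hbond: float = 1.0
    w_restraint: float = 4.0
    # local stiffness: flat-bottom band on virtual bond angles (radians)
    angle_lo: float = np.deg2rad(72.0)
    angle_hi: float = np.deg2rad(150.0)
    angle_kappa: float = 5.0
    # short-range statistical tables (None disables the term)
    short_range: ShortRangeTables | None = None
    # contacts
    contact_matrix: np.ndarray = field(default_factory=default_contact_matrix)
    contact_base: float = 4.5
    contact_offset_scale: float = 0.25  # range = base + scale·(d_sc,a + d_sc,b)
    orientation_floor: float = 0.3
    # excluded volume: per-class hard-core radii (Å); additive pair cores,
    # overridden for cross-class pairs where the pseudoatom construction
    # legitimately brings classes closer (side chains hug the backbone)
    ev_radii: dict = field(
        default_factory=lambda: {"CA": CA_CA_HARDCORE / 2, "CB": 0.7, "SC": 0.6}
    )
    ev_pair_min: dict = field(
        default_factory=lambda: {
            ("CA", "CB"): 1.6, ("CA", "SC"): 1.2, ("CB", "SC"): 1.2,
        }
    )
    # hydrogen bonds between mid-bond centers
    hb_dmin: float = 4.0
    hb_dmax: float = 5.5
    hb_min_cos: float = 0.5
    hb_depth: float = 1.0

    def __post_init__(self) -> None:
        self.contact_matrix = np.asarray(self.contact_matrix, dtype=float)
        if not np.allclose(self.contact_matrix, self.contact_matrix.T):
            raise ValueError("contact matrix must be symmetric")
        if any(r <= 0 for r in self.ev_radii.values()):
            raise ValueError("excluded-volume radii must be positive")

    # -- parameter file I/O (YAML: scalars + matrix blocks) -----------------

    _SCALARS = (
        "w_local", "w_short", "w_contact", "w_excluded", "w_hbond",
        "w_restraint", "angle_lo", "angle_hi", "angle_kappa",
        "contact_base", "contact_offset_scale", "orientation_floor",
        "hb_dmin", "hb_dmax", "hb_min_cos", "hb_depth",
    )

    def to_yaml(self, path) -> None:
        import yaml

        data = {k: float(getattr(self, k)) for k in self._SCALARS}
        data["ev_radii"] = {k: float(v) for k, v in self.ev_radii.items()}
        data["ev_pair_min"] = {
            f"{a}-{b}": float(v) for (a, b), v in self.ev_pair_min.items()
        }
        data["contact_matrix"] = self.contact_matrix.tolist()
        if self.short_range is not None:
            data["short_range"] = {
                "bin_edges": self.short_range.bin_edges.tolist(),
                "tables": {
                    f"{k}:{ca}:{cb}": tab.tolist()
                    for (k, (ca, cb)), tab in self.short_range.tables.items()
                },
            }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ForceField":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        kw = {k: data[k] for k in cls._SCALARS if k in data}
        if "ev_radii" in data:
            kw["ev_radii"] = dict(data["ev_radii"])
        if "ev_pair_min" in data:
            kw["ev_pair_min"] = {
                tuple(k.split("-")): v for k, v in data["ev_pair_min"].items()
            }
        if "contact_matrix" in data:
            kw["contact_matrix"] = np.asarray(data["contact_matrix"])
        ff = cls(**kw)
        if "short_range" in data:
            sr = data["short_range"]
            tables = {}
            for key, tab in sr["tables"].items():
                k, ca, cb = key.split(":")
                tables[(int(k), (ca, cb))] = np.asarray(tab, dtype=float)
            ff.short_range = ShortRangeTables(
                bin_edges=np.asarray(sr["bin_edges"], dtype=float),
                tables=tables,
            )
        return ff


_DEFAULT_FF: ForceField | None = None


def default_force_field() -> ForceField:
    """Shipped default force field; short-range tables are derived once from
    packaged helix fixtures (deterministic seeds) and cached."""
    global _DEFAULT_FF
    if _DEFAULT_FF is None:
        from .fixtures import make_ideal_helix
        from .lattice import default_lattice, project_chain, to_angstrom

        lat = default_lattice()
        traces = []
        for s in range(10):
            xyz, _ = make_ideal_helix(40, seed=s)
            tr, _err = project_chain(xyz, lat)
            traces.append(to_angstrom(tr, lat))  # lattice-cast statistics
        ff = ForceField()
        ff.short_range = derive_short_range_tables(traces, cap=2.0)
        _DEFAULT_FF = ff
    return _DEFAULT_FF


# ---------------------------------------------------------------------------
# individual terms
# ---------------------------------------------------------------------------


def local_stiffness_energy(chain: CGChain, ff: ForceField) -> float:
    """Flat-bottom penalty on virtual Cα bond angles; zero inside the
    protein-like band, quadratic outside."""
    ca = chain.ca
    if len(ca) < 3:
        return 0.0
    v1 = ca[:-2] - ca[1:-1]
    v2 = ca[2:] - ca[1:-1]
    cosang = (v1 * v2).sum(axis=1) / (
        np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
    )
    theta = np.arccos(np.clip(cosang, -1.0, 1.0))
    lo = np.maximum(0.0, ff.angle_lo - theta)
    hi = np.maximum(0.0, theta - ff.angle_hi)
    return float(ff.angle_kappa * (lo**2 + hi**2).sum())


def short_range_energy(chain: CGChain, ff: ForceField) -> float:
    """Sum of the binned (i, i+k) statistical potentials, k in {2, 3, 4}."""
    if ff.short_range is None:
        return 0.0
    ca = chain.ca
    edges = ff.short_range.bin_edges
    nbins = len(edges) - 1
    total = 0.0
    for k in (2, 3, 4):
        if len(ca) <= k:
            continue
        d = np.linalg.norm(ca[k:] - ca[:-k], axis=1)
        idx = np.clip(np.digitize(d, edges) - 1, 0, nbins - 1)
        table = ff.short_range.lookup(k, ("X", "X"))
        total += float(table[idx].sum())
    return total


def _seq_indices(seq: str) -> np.ndarray:
    return np.array([AMINO_ACIDS.index(a) for a in seq])


_PAIR_MASK_CACHE: dict = {}


def _chain_key(chains: list[CGChain]) -> tuple:
    return tuple((c.chain_id, c.sequence) for c in chains)


def _contact_masks(chains: list[CGChain]) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangular eligibility mask over residues (|i-j| >= 3 within a
    chain, all pairs across chains) and the flat residue-type index array."""
    key = ("contact", _chain_key(chains))
    if key not in _PAIR_MASK_CACHE:
        lens = [len(c) for c in chains]
        n = sum(lens)
        cidx = np.concatenate([np.full(l, k) for k, l in enumerate(lens)])
        ridx = np.concatenate([np.arange(l) for l in lens])
        same = cidx[:, None] == cidx[None, :]
        sep = np.abs(ridx[:, None] - ridx[None, :])
        mask = np.triu(np.ones((n, n), dtype=bool), k=1)
        mask &= ~(same & (sep < 3))
        aa = _seq_indices("".join(c.sequence for c in chains))
        _PAIR_MASK_CACHE[key] = (mask, aa)
    return _PAIR_MASK_CACHE[key]


def contact_energy(state: SystemState, ff: ForceField) -> float:
    """Side-chain pairwise contact energy with orientation scaling.

    A pair contributes matrix[a, b] scaled (attractive part only) by a factor
    from the angle between the two side-chain axes: 1 for antiparallel axes,
    decreasing linearly in cos to a floor for parallel (clashing) ones.
    """
    chains = state.chains
    mask, aa = _contact_masks(chains)
    sc = np.vstack([c.sc for c in chains])
    ca = np.vstack([c.ca for c in chains])
    sc_d = np.array([SC_DISTANCE[a] for c in chains for a in c.sequence])

    d = cdist(sc, sc)
    rng_cut = ff.contact_base + ff.contact_offset_scale * (
        sc_d[:, None] + sc_d[None, :]
    )
    pair = mask & (d < rng_cut)
    ii, jj = np.nonzero(pair)
    if ii.size == 0:
        return 0.0
    e = ff.contact_matrix[aa[ii], aa[jj]]

    axes = sc - ca
    norms = np.linalg.norm(axes, axis=1)
    ok = norms > 1e-9
    axes[ok] /= norms[ok, None]
    both = ok[ii] & ok[jj]
    cosang = np.where(both, (axes[ii] * axes[jj]).sum(axis=1), -1.0)
    factor = ff.orientation_floor + (1.0 - ff.orientation_floor) * (1.0 - cosang) / 2.0
    contrib = np.where(e < 0, e * factor, e)
    return float(contrib.sum())


def _ev_arrays(chains: list[CGChain], ff: ForceField):
    """Flat pseudoatom list (CA, CB, SC per residue; glycine has no CB/SC)
    with per-pair hard-core distances and the bonded-exemption mask."""
    key = ("ev", _chain_key(chains), tuple(sorted(ff.ev_radii.items())))
    if key not in _PAIR_MASK_CACHE:
        cls, cidx, ridx = [], [], []
        for k, c in enumerate(chains):
            for i, a in enumerate(c.sequence):
                cls.append("CA"); cidx.append(k); ridx.append(i)
                if a != "G":
                    cls.append("CB"); cidx.append(k); ridx.append(i)
                    cls.append("SC"); cidx.append(k); ridx.append(i)
        cidx = np.array(cidx)
        ridx = np.array(ridx)
        radii = np.array([ff.ev_radii[c] for c in cls])
        core = radii[:, None] + radii[None, :]
        for (a, b), dmin in ff.ev_pair_min.items():
            for p, q in ((a, b), (b, a)):
                sel = np.ix_(
                    [c == p for c in cls], [c == q for c in cls]
                )
                core[sel] = dmin
        same_chain = cidx[:, None] == cidx[None, :]
        sep = np.abs(ridx[:, None] - ridx[None, :])
        exempt = same_chain & (sep <= 1)  # same or adjacent residue
        check = np.triu(~exempt, k=1)
        _PAIR_MASK_CACHE[key] = (cls, core, check)
    return _PAIR_MASK_CACHE[key]


def _atom_coords(chains: list[CGChain]) -> np.ndarray:
    rows = []
    for c in chains:
        for i, a in enumerate(c.sequence):
            rows.append(c.ca[i])
            if a != "G":
                rows.append(c.cb[i])
                rows.append(c.sc[i])
    return np.asarray(rows)


def excluded_volume_energy(state: SystemState, ff: ForceField) -> float:
    """0 if every non-exempt pseudoatom pair clears its class hard core,
    +inf otherwise (hard rejection)."""
    chains = state.chains
    _, core, check = _ev_arrays(chains, ff)
    coords = _atom_coords(chains)
    d = cdist(coords, coords)
    if np.any(check & (d < core)):
        return INF
    return 0.0


def hbond_energy(obj, ff: ForceField) -> float:
    """Hydrogen-bond energy over mid-bond pseudoatom pairs.

    Pairs of virtual-bond centers at sequence separation >= 3 (or on
    different chains) within the distance window and with sufficiently
    collinear bond vectors each contribute -depth.  Always <= 0.
    """
    chains = obj.chains if isinstance(obj, SystemState) else [obj]
    hb, bonds, cidx, bidx = [], [], [], []
    for k, c in enumerate(chains):
        if len(c) < 2:
            continue
        hb.append(c.hb_center)
        bonds.append(c.ca[1:] - c.ca[:-1])
        cidx.append(np.full(len(c) - 1, k))
        bidx.append(np.arange(len(c) - 1))
    if not hb:
        return 0.0
    hb = np.vstack(hb)
    bonds = np.vstack(bonds)
    bonds = bonds / np.linalg.norm(bonds, axis=1, keepdims=True)
    cidx = np.concatenate(cidx)
    bidx = np.concatenate(bidx)

    d = cdist(hb, hb)
    same = cidx[:, None] == cidx[None, :]
    sep = np.abs(bidx[:, None] - bidx[None, :])
    eligible = np.triu(~(same & (sep < 3)), k=1)
    in_window = (d >= ff.hb_dmin) & (d <= ff.hb_dmax)
    collinear = np.abs(bonds @ bonds.T) >= ff.hb_min_cos
    n_pairs = int((eligible & in_window & collinear).sum())
    return -ff.hb_depth * n_pairs


# ---------------------------------------------------------------------------
# restraints
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Restraint:
    """Flat-bottom harmonic distance restraint between two Cα atoms.

    Residue indices are 0-based internally; file I/O is 1-based.
    """

    chain_i: str
    res_i: int
    chain_j: str
    res_j: int
    d0: float
    tol: float = 1.0
    k: float = 1.0

    def __post_init__(self) -> None:
        if self.d0 <= 0 or self.tol < 0 or self.k < 0:
            raise ValueError("restraint requires d0 > 0, tol >= 0, k >= 0")
        if self.chain_i == self.chain_j and self.res_i == self.res_j:
            raise ValueError("restraint cannot pair a residue with itself")


class RestraintSet:
    """A list of restraints with vectorised evaluation against a state."""

    def __init__(self, restraints: Iterable[Restraint] = ()):
        self.restraints = list(restraints)
        self._bound_key = None
        self._idx = None

    def __len__(self) -> int:
        return len(self.restraints)

    def _bind(self, state: SystemState) -> None:
        key = _chain_key(state.chains)
        if key == self._bound_key:
            return
        offset = {}
        pos = 0
        for c in state.chains:
            offset[c.chain_id] = pos
            pos += len(c)
        rows_i, rows_j, d0, tol, k = [], [], [], [], []
        for r in self.restraints:
            for cid, res in ((r.chain_i, r.res_i), (r.chain_j, r.res_j)):
                if cid not in offset:
                    raise KeyError(f"restraint references unknown chain {cid!r}")
            rows_i.append(offset[r.chain_i] + r.res_i)
            rows_j.append(offset[r.chain_j] + r.res_j)
            d0.append(r.d0); tol.append(r.tol); k.append(r.k)
        self._idx = (
            np.array(rows_i, dtype=int), np.array(rows_j, dtype=int),
            np.array(d0), np.array(tol), np.array(k),
        )
        self._bound_key = key

    def energy(self, state: SystemState) -> float:
        if not self.restraints:
            return 0.0
        self._bind(state)
        i, j, d0, tol, k = self._idx
        ca = np.vstack([c.ca for c in state.chains])
        d = np.linalg.norm(ca[i] - ca[j], axis=1)
        excess = np.maximum(0.0, np.abs(d - d0) - tol)
        return float((k * excess**2).sum())

    # -- text file I/O (chain res chain res d0 tol k; residues 1-based) -----

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for r in self.restraints:
                fh.write(
                    f"{r.chain_i} {r.res_i + 1} {r.chain_j} {r.res_j + 1} "
                    f"{r.d0:.4f} {r.tol:.4f} {r.k:.4f}\n"
                )

    @classmethod
    def from_file(cls, path) -> "RestraintSet":
        restraints = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                ci, ri, cj, rj, d0, tol, k = line.split()
                restraints.append(
                    Restraint(ci, int(ri) - 1, cj, int(rj) - 1,
                              float(d0), float(tol), float(k))
                )
        return cls(restraints)


def restraint_energy(state: SystemState, restraints: RestraintSet) -> float:
    """Sum of k·max(0, |d - d0| - tol)² over the restraint list."""
    return restraints.energy(state)


# ---------------------------------------------------------------------------
# total
# ---------------------------------------------------------------------------

TERM_NAMES = ("local", "short_range", "contact", "excluded_volume", "hbond",
              "restraint")


def total_energy(
    state: SystemState,
    ff: ForceField,
    restraints: RestraintSet | None = None,
) -> tuple[float, dict]:
    """Weighted total energy with the per-term breakdown (unweighted terms)."""
    ev = excluded_volume_energy(state, ff)
    terms = {
        "local": sum(local_stiffness_energy(c, ff) for c in state.chains),
        "short_range": sum(short_range_energy(c, ff) for c in state.chains),
        "contact": contact_energy(state, ff),
        "excluded_volume": ev,
        "hbond": hbond_energy(state, ff),
        "restraint": restraint_energy(state, restraints)
        if restraints is not None
        else 0.0,
    }
    if ev == INF:
        return INF, terms
    weights = {
        "local": ff.w_local,
        "short_range": ff.w_short,
        "contact": ff.w_contact,
        "excluded_volume": ff.w_excluded,
        "hbond": ff.w_hbond,
        "restraint": ff.w_restraint,
    }
    total = sum(weights[t] * terms[t] for t in TERM_NAMES)
    return float(total), terms
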