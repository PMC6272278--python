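"""Coarse-grained chain representation.

Each residue is represented by up to four pseudoatoms: the Cα on the lattice,
a Cβ at a fixed 1.53 Å offset, a side-chain center at a residue-specific
distance along the same local axis (for glycine the side-chain center
coincides with Cα), and — per virtual bond — a hydrogen-bond center at the
exact midpoint of consecutive Cα atoms.  Off-lattice pseudoatoms are
deterministic functions of the local Cα geometry and "follow" the backbone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .lattice import (
    BOND_LENGTH_MAX,
    LatticeModel,
    LatticeTrace,
    default_lattice,
    project_chain,
    to_angstrom,
)

CB_DISTANCE = 1.53  # Å, Cα → Cβ along the local outward axis
SC_TILT = np.deg2rad(35.0)  # out-of-plane tilt of the side-chain axis

# Cα → side-chain-center distances (Å), rotamer-averaged coarse-grained
# geometry for the 20 standard residues.
SC_DISTANCE = {
    "A": 1.53, "C": 2.05, "D": 2.47, "E": 3.11, "F": 3.41,
    "G": 0.00, "H": 3.15, "I": 2.31, "K": 3.52, "L": 2.60,
    "M": 2.95, "N": 2.46, "P": 1.87, "Q": 3.09, "R": 4.11,
    "S": 1.90, "T": 1.93, "V": 1.97, "W": 3.86, "Y": 3.84,
}

AA_1TO3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
AA_3TO1 = {v: k for k, v in AA_1TO3.items()}


class StructureParseError(ValueError):
    """Raised when a structure file cannot be interpreted."""


def _unit(v: np.ndarray, axis: int = -1) -> np.ndarray:
    n = np.linalg.norm(v, axis=axis, keepdims=True)
    n = np.where(n < 1e-12, 1.0, n)
    return v / n


def _perpendicular_rows(u: np.ndarray) -> np.ndarray:
    """Deterministic unit vectors perpendicular to each row of u."""
    k = np.argmin(np.abs(u), axis=1)
    e = np.eye(3)[k]
    return _unit(np.cross(u, e))


def pseudoatoms_from_ca(
    ca: np.ndarray, sequence: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Place Cβ, side-chain and H-bond pseudoatoms from Å Cα coordinates.

    The local axis at interior residue i points opposite the bisector of the
    two virtual bonds leaving i, tilted out of the backbone plane by a fixed
    angle; termini copy the axis of the adjacent interior residue.
    Fully vectorised: this runs on every Monte Carlo energy evaluation.
    """
    ca = np.asarray(ca, dtype=float)
    n = len(ca)
    if n < 3:
        raise ValueError("pseudoatom frames need at least 3 residues")
    if len(sequence) != n:
        raise ValueError("sequence length does not match trace length")

    u1 = _unit(ca[:-2] - ca[1:-1])
    u2 = _unit(ca[2:] - ca[1:-1])
    bis = u1 + u2
    bis_ok = np.linalg.norm(bis, axis=1) > 1e-8
    # collinear backbone: the bisector degenerates; fall back to a
    # deterministic perpendicular of the forward bond
    out = np.where(bis_ok[:, None], -_unit(bis), _perpendicular_rows(u2))
    out = _unit(out)
    normal = np.cross(u1, u2)
    norm_ok = np.linalg.norm(normal, axis=1) > 1e-8
    normal = np.where(norm_ok[:, None], _unit(normal), _perpendicular_rows(out))
    dirs = np.empty((n, 3))
    dirs[1:-1] = np.cos(SC_TILT) * out + np.sin(SC_TILT) * normal
    dirs[0] = dirs[1]
    dirs[-1] = dirs[-2]
    dirs = _unit(dirs)

    cb = ca + CB_DISTANCE * dirs
    try:
        sc_d = np.array([SC_DISTANCE[a] for a in sequence])
    except KeyError as exc:
        raise ValueError(f"unknown residue letter {exc.args[0]!r}") from None
    sc = ca + sc_d[:, None] * dirs
    hb = 0.5 * (ca[:-1] + ca[1:])
    return cb, sc, hb


@dataclass
class CGChain:
    """One polymer chain in the coarse-grained representation."""

    sequence: str
    trace: LatticeTrace
    ca: np.ndarray = field(repr=False)
    cb: np.ndarray = field(repr=False)
    sc: np.ndarray = field(repr=False)
    hb_center: np.ndarray = field(repr=False)
    flexibility: np.ndarray = field(default=None, repr=False)  # bool: restrained?

    def __post_init__(self) -> None:
        if self.flexibility is None:
            self.flexibility = np.zeros(len(self.sequence), dtype=bool)

    @property
    def chain_id(self) -> str:
        return self.trace.chain_id

    def __len__(self) -> int:
        return len(self.sequence)

    def refresh(self, lattice: LatticeModel | None = None) -> None:
        """Recompute Å coordinates and pseudoatoms from the lattice trace."""
        self.ca = to_angstrom(self.trace, lattice or default_lattice())
        self.cb, self.sc, self.hb_center = pseudoatoms_from_ca(self.ca, self.sequence)

    def copy(self) -> "CGChain":
        return CGChain(
            sequence=self.sequence,
            trace=LatticeTrace(self.trace.positions.copy(), self.trace.chain_id),
            ca=self.ca.copy(),
            cb=self.cb.copy(),
            sc=self.sc.copy(),
            hb_center=self.hb_center.copy(),
            flexibility=self.flexibility.copy(),
        )


def rebuild_pseudoatoms(
    trace: LatticeTrace, sequence: str, lattice: LatticeModel | None = None
) -> CGChain:
    """Build a CGChain from a lattice Cα trace and a one-letter sequence."""
    if len(sequence) != len(trace):
        raise ValueError("sequence length does not match trace length")
    if len(sequence) < 3:
        raise ValueError("chain must have at least 3 residues")
    ca = to_angstrom(trace, lattice or default_lattice())
    cb, sc, hb = pseudoatoms_from_ca(ca, sequence)
    return CGChain(sequence=sequence, trace=trace, ca=ca, cb=cb, sc=sc, hb_center=hb)


@dataclass
class SystemState:
    """Receptor chain(s) plus an optional peptide ligand."""

    receptor: list[CGChain]
    ligand: CGChain | None = None
    energy_terms: dict = field(default_factory=dict)
    total_energy: float = 0.0

    @property
    def chains(self) -> list[CGChain]:
        return self.receptor + ([self.ligand] if self.ligand is not None else [])

    def copy(self) -> "SystemState":
        return SystemState(
            receptor=[c.copy() for c in self.receptor],
            ligand=self.ligand.copy() if self.ligand is not None else None,
            energy_terms=dict(self.energy_terms),
            total_energy=self.total_energy,
        )


# ---------------------------------------------------------------------------
# PDB input / output
# ---------------------------------------------------------------------------


def read_structure(
    path,
    mode: str = "calpha",
    lattice: LatticeModel | None = None,
) -> tuple[list[CGChain], list[np.ndarray]]:
    """Read a PDB file into CGChains plus the raw Cα coordinates (Å).

    Sequences come from residue names; each chain's Cα trace is projected
    onto the lattice and pseudoatoms are rebuilt deterministically.  Chain
    breaks (consecutive Cα farther than 4.8 Å apart) are reported as parse
    errors naming the offending residues.  ``mode="full"`` additionally
    requires the CB/SC pseudoatom records written by :func:`write_structure`.
    """
    if mode not in ("calpha", "full"):
        raise ValueError("mode must be 'calpha' or 'full'")
    lattice = lattice or default_lattice()
    try:
        pdb = PDBFile.read(str(path))
        atoms = pdb.get_structure(model=1)
    except Exception as exc:  # biotite parse failure
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc

    chains: list[CGChain] = []
    raw: list[np.ndarray] = []
    seen = []
    for cid in atoms.chain_id:
        if cid not in seen:
            seen.append(cid)
    for cid in seen:
        sub = atoms[atoms.chain_id == cid]
        ca_mask = sub.atom_name == "CA"
        if not ca_mask.any():
            raise StructureParseError(f"chain {cid!r} has no CA atoms")
        ca_atoms = sub[ca_mask]
        coords = ca_atoms.coord.astype(float)
        try:
            seq = "".join(AA_3TO1[rn] for rn in ca_atoms.res_name)
        except KeyError as exc:
            raise StructureParseError(
                f"chain {cid!r}: unknown residue name {exc.args[0]!r}"
            ) from None
        gaps = np.linalg.norm(np.diff(coords, axis=0), axis=1)
        broken = np.where(gaps > BOND_LENGTH_MAX)[0]
        if broken.size:
            i = int(broken[0])
            raise StructureParseError(
                f"chain {cid!r}: break between residues {i + 1} and {i + 2} "
                f"(Cα-Cα distance {gaps[i]:.2f} Å)"
            )
        if mode == "full":
            n_sc = int((sub.atom_name == "SC").sum())
            n_gly = sum(1 for s in seq if s == "G")
            if n_sc != len(seq) - n_gly:
                raise StructureParseError(
                    f"chain {cid!r}: expected {len(seq) - n_gly} SC records, "
                    f"found {n_sc}"
                )
        trace, _ = project_chain(coords, lattice, chain_id=cid)
        chains.append(rebuild_pseudoatoms(trace, seq, lattice))
        raw.append(coords)
    return chains, raw


def _chains_to_atom_array(chains: list[CGChain], pseudoatoms: bool) -> struc.AtomArray:
    records = []
    for chain in chains:
        for i, aa in enumerate(chain.sequence):
            records.append((chain.chain_id, i + 1, AA_1TO3[aa], "CA", chain.ca[i]))
            if pseudoatoms and aa != "G":
                records.append((chain.chain_id, i + 1, AA_1TO3[aa], "CB", chain.cb[i]))
                records.append((chain.chain_id, i + 1, AA_1TO3[aa], "SC", chain.sc[i]))
    arr = struc.AtomArray(len(records))
    arr.coord = np.array([r[4] for r in records], dtype=np.float32)
    arr.chain_id = np.array([r[0] for r in records])
    arr.res_id = np.array([r[1] for r in records])
    arr.res_name = np.array([r[2] for r in records])
    arr.atom_name = np.array([r[3] for r in records])
    arr.element = np.array(["C"] * len(records))
    arr.hetero = np.zeros(len(records), dtype=bool)
    arr.set_annotation("occupancy", np.ones(len(records), dtype=float))
    arr.set_annotation("b_factor", np.zeros(len(records), dtype=float))
    return arr


def write_structure(
    chains,
    path,
    multi_model: bool = False,
    pseudoatoms: bool = True,
) -> None:
    """Write chains (or, with ``multi_model``, a list of frames of chains)
    as a PDB file; frames become MODEL/ENDMDL blocks."""
    if multi_model:
        frames = list(chains)
        if not frames or not frames[0]:
            raise ValueError("no chains to write")
        arrays = [_chains_to_atom_array(f, pseudoatoms) for f in frames]
        stack = struc.stack(arrays)
        pdb = PDBFile()
        pdb.set_structure(stack)
    else:
        chains = list(chains)
        if not chains:
            raise ValueError("no chains to write")
        pdb = PDBFile()
        pdb.set_structure(_chains_to_atom_array(chains, pseudoatoms))
    pdb.write(str(path))
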