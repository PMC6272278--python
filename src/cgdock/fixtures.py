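"""Synthetic structures and trajectories with known ground truth.

Everything other modules need for testing is generated here at run time:
ideal α-helices, protein-like self-avoiding random coils, toy two-domain
receptors joined by an extended linker (emulating a two-domain calcium
sensor bound by a ~30-residue helical peptide), and planted trajectories
drawn from known conformer mixtures.  No external downloads.

Domain sequences follow a hydrophobic-core/polar-surface pattern and
linkers an alternating polar pattern; this gives the contact term
meaningful structure without claiming realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sampling import Frame, Trajectory

HELIX_RISE = 1.5  # Å per residue
HELIX_TWIST = np.deg2rad(100.0)  # per residue
HELIX_RADIUS = 2.3  # Å

BOND = 3.8  # Å, target virtual bond length
MIN_SEP = 4.1  # Å, self-avoidance between non-adjacent Cα during generation
# Confinement radius for globule-like domains: R = coeff * n^(1/3), chosen
# so generated chains approach folded-protein packing density.
DOMAIN_RADIUS_COEFF = 2.75

_HYDROPHOBIC = "LIVFMA"
_POLAR = "KEQNSD"


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation (QR-based, deterministic in rng)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _amphipathic_sequence(n: int, rng: np.random.Generator) -> str:
    """Helical-periodicity sequence: hydrophobic on one face, polar on the
    other."""
    seq = []
    for i in range(n):
        phase = (i * 100.0) % 360.0
        pool = _HYDROPHOBIC if phase < 180.0 else _POLAR
        seq.append(pool[int(rng.integers(len(pool)))])
    return "".join(seq)


def make_ideal_helix(n_res: int, seed: int = 0) -> tuple[np.ndarray, str]:
    """Ideal α-helical Cα trace (rise 1.5 Å, 100°/residue, radius 2.3 Å)
    in a seeded random rigid orientation, with an amphipathic sequence.
    Consecutive Cα distances are ~3.83 Å."""
    if n_res < 4:
        raise ValueError("helix needs at least 4 residues")
    rng = np.random.default_rng(seed)
    t = np.arange(n_res) * HELIX_TWIST
    xyz = np.column_stack(
        [HELIX_RADIUS * np.cos(t), HELIX_RADIUS * np.sin(t),
         HELIX_RISE * np.arange(n_res)]
    )
    xyz = xyz - xyz.mean(axis=0)
    xyz = xyz @ _random_rotation(rng).T + rng.uniform(-20, 20, size=3)
    return xyz, _amphipathic_sequence(n_res, rng)


def _grow_saw(
    n_res: int,
    rng: np.random.Generator,
    start: np.ndarray,
    first_dir: np.ndarray | None = None,
    confine_center: np.ndarray | None = None,
    confine_radius: float = np.inf,
    avoid: np.ndarray | None = None,
    angle_lo: float = np.deg2rad(75.0),
    angle_hi: float = np.deg2rad(165.0),
    max_tries: int = 300,
) -> np.ndarray | None:
    """Grow a self-avoiding 3.8 Å chain with protein-like bond angles,
    optionally confined to a sphere and avoiding earlier coordinates.
    Returns None on packing failure (caller retries with a new substream)."""
    pts = [np.asarray(start, dtype=float)]
    prior = avoid if avoid is not None else np.empty((0, 3))
    for i in range(1, n_res):
        placed = False
        for _ in range(max_tries):
            if i == 1:
                d = first_dir if first_dir is not None else rng.normal(size=3)
                d = np.asarray(d, dtype=float)
                d = d / np.linalg.norm(d)
                if first_dir is None:
                    pass
            else:
                d = rng.normal(size=3)
                d = d / np.linalg.norm(d)
                prev = pts[-1] - pts[-2]
                prev = prev / np.linalg.norm(prev)
                cosang = float(d @ -prev)
                theta = np.arccos(np.clip(cosang, -1, 1))
                if not (angle_lo <= theta <= angle_hi):
                    continue
            cand = pts[-1] + BOND * d
            if confine_center is not None:
                if np.linalg.norm(cand - confine_center) > confine_radius:
                    continue
            own = np.array(pts[:-1]) if len(pts) > 1 else np.empty((0, 3))
            clashes = np.vstack([own, prior]) if len(own) or len(prior) else None
            if clashes is not None and len(clashes):
                if np.min(np.linalg.norm(clashes - cand, axis=1)) < MIN_SEP:
                    continue
            pts.append(cand)
            placed = True
            break
        if not placed:
            return None
    return np.array(pts)


def _ev_clean(coords: np.ndarray, sequence: str) -> bool:
    """True when the lattice-projected CG representation of these Cα
    coordinates clears the excluded-volume hard cores, i.e. the structure
    is a valid Monte Carlo starting state."""
    from .energy import ForceField, excluded_volume_energy
    from .lattice import default_lattice, project_chain
    from .representation import SystemState, rebuild_pseudoatoms

    lat = default_lattice()
    try:
        trace, _ = project_chain(coords, lat)
    except Exception:
        return False
    chain = rebuild_pseudoatoms(trace, sequence, lat)
    return excluded_volume_energy(SystemState(receptor=[chain]), ForceField()) == 0.0


def make_random_coil(n_res: int, seed: int = 0) -> tuple[np.ndarray, str]:
    """Protein-like self-avoiding random chain: 3.8 Å bonds, bond angles in
    the protein band, no two non-adjacent Cα closer than the hard core."""
    if n_res < 3:
        raise ValueError("coil needs at least 3 residues")
    seq_rng = np.random.default_rng(np.random.SeedSequence((seed, 999)))
    alphabet = _HYDROPHOBIC + _POLAR
    seq = "".join(
        alphabet[int(seq_rng.integers(len(alphabet)))] for _ in range(n_res)
    )
    for attempt in range(50):
        rng = np.random.default_rng(np.random.SeedSequence((seed, attempt)))
        coords = _grow_saw(n_res, rng, start=rng.uniform(-5, 5, size=3))
        if coords is not None and _ev_clean(coords, seq):
            return coords, seq
    raise RuntimeError("could not grow a self-avoiding coil")


def make_compact_domain(n_res: int, seed: int = 0) -> tuple[np.ndarray, str]:
    """A single compact globule-like domain (self-avoiding chain confined
    to a sphere), a valid Monte Carlo starting state."""
    if n_res < 10:
        raise ValueError("domain needs at least 10 residues")
    radius = DOMAIN_RADIUS_COEFF * n_res ** (1 / 3)
    for attempt in range(100):
        rng = np.random.default_rng(np.random.SeedSequence((seed, attempt)))
        coords = _grow_saw(
            n_res, rng, start=rng.uniform(-2, 2, size=3),
            confine_center=np.zeros(3), confine_radius=radius,
        )
        if coords is None:
            continue
        seq = _domain_sequence(n_res, rng)
        if _ev_clean(coords, seq):
            return coords, seq
    raise RuntimeError("could not pack a compact domain")


def _domain_sequence(n: int, rng: np.random.Generator) -> str:
    """Roughly half hydrophobic (core) and half polar (surface) residues."""
    seq = []
    for i in range(n):
        pool = _HYDROPHOBIC if rng.random() < 0.5 else _POLAR
        seq.append(pool[int(rng.integers(len(pool)))])
    return "".join(seq)


def _helix_arc(n: int, phase: float = 0.0, handed: float = 1.0) -> np.ndarray:
    t = handed * (np.arange(n) * HELIX_TWIST + phase)
    return np.column_stack(
        [HELIX_RADIUS * np.cos(t), HELIX_RADIUS * np.sin(t),
         HELIX_RISE * np.arange(n)]
    )


def _bezier_turn(p_from: np.ndarray, p_to: np.ndarray, n_points: int,
                 up: np.ndarray) -> np.ndarray | None:
    """Interior points of a quadratic Bézier turn from p_from to p_to whose
    apex height is tuned so consecutive spacings are protein-like."""
    n_seg = n_points + 1
    for height in np.arange(0.0, 14.0, 0.25):
        ctrl = 0.5 * (p_from + p_to) + height * up
        t = np.linspace(0.0, 1.0, 200)
        curve = ((1 - t)[:, None] ** 2 * p_from + 2 * ((1 - t) * t)[:, None]
                 * ctrl + (t**2)[:, None] * p_to)
        seg = np.linalg.norm(np.diff(curve, axis=0), axis=1)
        arc = seg.sum()
        step = arc / n_seg
        if not (3.2 <= step <= 4.3):
            continue
        # resample at equal arc length
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        pts = []
        for k in range(1, n_seg):
            idx = np.searchsorted(cum, k * step)
            idx = min(idx, len(curve) - 1)
            pts.append(curve[idx])
        out = np.array(pts)
        d = np.linalg.norm(np.diff(
            np.vstack([p_from, out, p_to]), axis=0), axis=1)
        if np.all((d > 2.95) & (d < 4.75)):
            return out
    return None


def make_helix_bundle_domain(
    n_res: int, seed: int = 0, turn_len: int = 4
) -> tuple[np.ndarray, str]:
    """A compact antiparallel two-helix bundle domain.

    This is the fixture analogue of a small all-α domain (the architecture
    of calcium-sensor lobes): two packed helices joined by a tight turn.
    Because the shipped short-range tables, hydrogen-bond term and local
    stiffness all have their minima at helical geometry, the native state
    of this fixture is a genuine basin of the force field, as for a real
    folded domain.
    """
    if n_res < 14:
        raise ValueError("bundle domain needs at least 14 residues")
    n1 = (n_res - turn_len) // 2
    n2 = n_res - turn_len - n1
    for attempt in range(200):
        rng = np.random.default_rng(np.random.SeedSequence((seed, attempt)))
        h1 = _helix_arc(n1, phase=rng.uniform(0, 2 * np.pi))
        sep = rng.uniform(8.6, 10.2)
        ang = rng.uniform(0, 2 * np.pi)
        offset = np.array([sep * np.cos(ang), sep * np.sin(ang), 0.0])
        h2 = _helix_arc(n2, phase=rng.uniform(0, 2 * np.pi), handed=-1.0)
        h2 = h2[::-1]  # runs antiparallel, top to bottom
        z_shift = h1[-1, 2] - h2[0, 2] + rng.uniform(-1.5, 0.5)
        h2 = h2 + offset + np.array([0.0, 0.0, z_shift])
        up = np.array([0.0, 0.0, 1.0])
        turn = _bezier_turn(h1[-1], h2[0], turn_len, up)
        if turn is None:
            continue
        coords = np.vstack([h1, turn, h2])
        # self-avoidance across segments
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(coords))
        n = len(coords)
        nonadj = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :]) >= 2
        if d[nonadj].min() < MIN_SEP - 0.4:
            continue
        # random rigid placement
        coords = coords - coords.mean(axis=0)
        coords = coords @ _random_rotation(rng).T + rng.uniform(-8, 8, size=3)
        seq = (_amphipathic_sequence(n1, rng)
               + ("GSNS" * turn_len)[:turn_len]
               + _amphipathic_sequence(n2, rng))
        if _ev_clean(coords, seq):
            return coords, seq
    raise RuntimeError("could not build a helix-bundle domain")


def make_two_domain_receptor(
    n1: int = 40, linker_len: int = 6, n2: int = 40, seed: int = 0
) -> tuple[np.ndarray, str, dict]:
    """Two compact globule-like domains joined by an extended linker.

    Returns (coords, sequence, annotations); annotations carry the 0-based
    inclusive residue ranges of the two domains and the linker, ready for
    flexibility configs and RMSD selections.
    """
    if n1 < 14 or n2 < 14:
        raise ValueError("domains need at least 14 residues")
    if linker_len < 3:
        raise ValueError("linker needs at least 3 residues")
    for attempt in range(100):
        rng = np.random.default_rng(np.random.SeedSequence((seed, attempt)))
        s1 = int(rng.integers(2**31))
        s2 = int(rng.integers(2**31))
        try:
            dom1, seq1 = make_helix_bundle_domain(n1, seed=s1)
            dom2_raw, seq2 = make_helix_bundle_domain(n2, seed=s2)
        except RuntimeError:
            continue
        # extended linker leaving domain 1 radially
        out_dir = dom1[-1] - dom1.mean(axis=0)
        out_dir = out_dir / max(np.linalg.norm(out_dir), 1e-9)
        linker = _grow_saw(
            linker_len + 1, rng, start=dom1[-1], first_dir=out_dir,
            angle_lo=np.deg2rad(130.0), angle_hi=np.deg2rad(178.0),
            avoid=dom1[:-1],
        )
        if linker is None:
            continue
        linker = linker[1:]  # drop the shared start point
        # rigid-place the second bundle so its first residue continues the
        # chain along the linker direction
        anchor = linker[-1] + BOND * out_dir
        placed = None
        for _ in range(40):
            rot = _random_rotation(rng)
            cand = (dom2_raw - dom2_raw[0]) @ rot.T + anchor
            prior = np.vstack([dom1, linker])
            dmin = np.min(np.linalg.norm(
                prior[:, None, :] - cand[None, 1:, :], axis=2))
            if dmin >= MIN_SEP - 0.2:
                placed = cand
                break
        if placed is None:
            continue
        dom2 = placed
        coords = np.vstack([dom1, linker, dom2])
        seq = seq1 + ("GS" * linker_len)[:linker_len] + seq2
        if not _ev_clean(coords, seq):
            continue
        annotations = {
            "domains": [(0, n1 - 1), (n1 + linker_len, n1 + linker_len + n2 - 1)],
            "linker": (n1, n1 + linker_len - 1),
        }
        return coords, seq, annotations
    raise RuntimeError("could not pack a two-domain receptor")


@dataclass
class PlantedTrajectorySpec:
    """Mixture-of-conformers trajectory with ground-truth labels."""

    conformers: list  # (n, 3) Å coordinate arrays, one chain
    weights: dict  # temperature -> sequence of mixture weights
    n_frames: int = 200  # per temperature
    jitter_sigma: float = 0.0  # Å, isotropic Gaussian coordinate noise
    seed: int = 0
    sequence: str | None = None
    chain_id: str = "A"

    def __post_init__(self) -> None:
        if not self.conformers:
            raise ValueError("need at least one conformer")
        n = len(self.conformers[0])
        if any(len(c) != n for c in self.conformers):
            raise ValueError("conformers must have equal length")
        if n < 3:
            raise ValueError("conformers need >= 3 residues")
        for t, w in self.weights.items():
            w = np.asarray(w, dtype=float)
            if len(w) != len(self.conformers) or not np.isclose(w.sum(), 1.0):
                raise ValueError(f"weights at T={t} must sum to 1")


def make_planted_trajectory(spec: PlantedTrajectorySpec) -> Trajectory:
    """Draw frames from the stated conformer mixture per temperature, with
    optional Gaussian jitter; the generating conformer index is stored as
    each frame's ground-truth label."""
    rng = np.random.default_rng(spec.seed)
    n = len(spec.conformers[0])
    seq = spec.sequence or "A" * n
    traj = Trajectory(chain_meta=[(spec.chain_id, seq)])
    temps = sorted(spec.weights)
    step = 0
    for ri, t in enumerate(temps):
        w = np.asarray(spec.weights[t], dtype=float)
        labels = rng.choice(len(spec.conformers), size=spec.n_frames, p=w)
        for label in labels:
            xyz = np.asarray(spec.conformers[label], dtype=float).copy()
            if spec.jitter_sigma > 0:
                xyz = xyz + rng.normal(scale=spec.jitter_sigma, size=xyz.shape)
            traj.frames.append(
                Frame(replica=ri, temperature=float(t), step=step,
                      coords=[xyz], energy=0.0, label=int(label))
            )
            step += 1
    return traj
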