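"""Trajectory analysis.

RMSD machinery (Kabsch superposition, residue-range selections, the
RMSD / RMSD_bound / RMSD_domains conventions), near-native transition
curves, 2D conformational density maps, residue contact profiles, radius
of gyration, inter-residue distance series, Gaussian kernel density
estimation, and RMSD-based linkage clustering of structural ensembles.

Selections are strings ``"chain:start-end[,start-end]"`` with 1-based
inclusive residue ranges; several chains may be joined with ``;``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, squareform

from .representation import CGChain, SystemState
from .sampling import Frame, Trajectory

# ---------------------------------------------------------------------------
# selections
# ---------------------------------------------------------------------------


def parse_selection(sel) -> list[tuple[str, list[tuple[int, int]]]]:
    """Parse ``"A:3-33"`` / ``"A:1-10,20-30;B:1-8"`` into
    [(chain, [(start, end), ...]), ...] with 1-based inclusive bounds."""
    if isinstance(sel, (list, tuple)):
        out = []
        for s in sel:
            out.extend(parse_selection(s))
        return out
    out = []
    for part in str(sel).split(";"):
        part = part.strip()
        if not part:
            continue
        chain, _, ranges = part.partition(":")
        if not ranges:
            raise ValueError(f"selection {part!r} needs 'chain:start-end'")
        spans = []
        for r in ranges.split(","):
            lo, _, hi = r.partition("-")
            lo = int(lo)
            hi = int(hi) if hi else lo
            if lo < 1 or hi < lo:
                raise ValueError(f"bad residue range {r!r}")
            spans.append((lo, hi))
        out.append((chain.strip(), spans))
    return out


def _resolve(structure: dict, sel) -> np.ndarray:
    """Gather the selected Cα coordinates from {chain_id: (n, 3) array}."""
    rows = []
    for chain, spans in parse_selection(sel):
        if chain not in structure:
            raise KeyError(f"selection references missing chain {chain!r}")
        coords = structure[chain]
        for lo, hi in spans:
            if hi > len(coords):
                raise KeyError(
                    f"selection {chain}:{lo}-{hi} exceeds chain length "
                    f"{len(coords)}"
                )
            rows.append(coords[lo - 1:hi])
    return np.vstack(rows)


def frame_structure(traj: Trajectory, frame: Frame) -> dict:
    """{chain_id: Cα coordinates} view of one frame."""
    return {cid: xyz for (cid, _), xyz in zip(traj.chain_meta, frame.coords)}


# ---------------------------------------------------------------------------
# superposition and RMSD
# ---------------------------------------------------------------------------


@dataclass
class SuperposeResult:
    rotation: np.ndarray  # (3, 3) proper rotation
    translation: np.ndarray  # applied after rotation about the centroid
    rmsd: float
    translation_only: bool = False  # degenerate input fallback

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return (coords - self.mobile_mean) @ self.rotation.T + self.reference_mean

    mobile_mean: np.ndarray = field(default=None)
    reference_mean: np.ndarray = field(default=None)


def superpose(mobile: np.ndarray, reference: np.ndarray) -> SuperposeResult:
    """Least-squares optimal rigid superposition (Kabsch, proper rotation).

    Collinear or <3-point inputs fall back to translation-only with the
    ``translation_only`` flag set.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or len(mobile) == 0:
        raise ValueError("point sets must be equal-length, non-empty (n, 3)")
    mm, rm = mobile.mean(axis=0), reference.mean(axis=0)
    x, y = mobile - mm, reference - rm

    degenerate = len(mobile) < 3
    if not degenerate:
        # collinearity: second singular value of the centred mobile set ~ 0
        s = np.linalg.svd(x, compute_uv=False)
        degenerate = s[1] < 1e-8 * max(s[0], 1.0)
    if degenerate:
        d = x - y
        rmsd = float(np.sqrt((d * d).sum() / len(mobile)))
        return SuperposeResult(np.eye(3), rm - mm, rmsd, True, mm, rm)

    h = x.T @ y
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    diff = x @ rot.T - y
    rmsd = float(np.sqrt((diff * diff).sum() / len(mobile)))
    return SuperposeResult(rot, rm - rot @ mm, rmsd, False, mm, rm)


@dataclass
class RMSDSpec:
    """What to measure and what to fit on.

    ``selection`` is measured; ``superpose_on`` (default: the same) is used
    for the least-squares fit.  The three standard docking metrics are this
    with different selections: the whole receptor+peptide (near-native RMSD),
    both receptor domains, and the bound C-domain+peptide subset.
    """

    selection: object
    superpose_on: object | None = None


def rmsd_metric(mobile: dict, reference: dict, spec: RMSDSpec) -> float:
    """Superpose on ``spec.superpose_on`` and measure Cα RMSD over
    ``spec.selection``; structures are {chain_id: coordinates} maps."""
    fit_sel = spec.superpose_on if spec.superpose_on is not None else spec.selection
    fit_m, fit_r = _resolve(mobile, fit_sel), _resolve(reference, fit_sel)
    res = superpose(fit_m, fit_r)
    meas_m = _resolve(mobile, spec.selection)
    meas_r = _resolve(reference, spec.selection)
    if res.translation_only:
        moved = meas_m + (res.reference_mean - res.mobile_mean)
    else:
        moved = res.apply(meas_m)
    diff = moved - meas_r
    return float(np.sqrt((diff * diff).sum() / len(diff)))


# ---------------------------------------------------------------------------
# ensemble measures
# ---------------------------------------------------------------------------


@dataclass
class TransitionCurve:
    temperatures: np.ndarray
    fractions: np.ndarray  # fraction of near-native frames per temperature
    threshold: float = 6.0
    counts: np.ndarray = None  # frames per temperature

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("temperature\tfraction\tn_frames\n")
            for t, f, n in zip(self.temperatures, self.fractions, self.counts):
                fh.write(f"{t:g}\t{f:.6f}\t{n}\n")


def transition_curve(
    traj: Trajectory,
    reference: dict,
    spec: RMSDSpec,
    threshold: float = 6.0,
    second_half: bool = True,
) -> TransitionCurve:
    """Per-temperature fraction of frames whose RMSD (per ``spec``) to the
    reference is below ``threshold``.  Temperatures with no frames are
    omitted.  Monotonicity is not assumed."""
    temps = sorted({f.temperature for f in traj.frames})
    ts, fracs, counts = [], [], []
    for t in temps:
        frames = traj.select(temperature=t, second_half=second_half)
        if not frames:
            continue
        vals = np.array(
            [rmsd_metric(frame_structure(traj, f), reference, spec) for f in frames]
        )
        ts.append(t)
        fracs.append(float((vals < threshold).mean()))
        counts.append(len(vals))
    return TransitionCurve(np.array(ts), np.array(fracs), threshold,
                           np.array(counts))


@dataclass
class DensityMap2D:
    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray
    density: np.ndarray  # per-cell normalised
    x_label: str = "RMSD_bound"
    y_label: str = "RMSD_domains"

    def to_tsv(self, path, normalised: bool = False) -> None:
        """Matrix TSV with bin-edge header row/column (counts by default)."""
        m = self.density if normalised else self.counts
        with open(path, "w") as fh:
            fh.write("x_edge\\y_edge\t" + "\t".join(
                f"{e:g}" for e in self.y_edges[:-1]) + "\n")
            for xe, row in zip(self.x_edges[:-1], m):
                fh.write(f"{xe:g}\t" + "\t".join(
                    f"{v:g}" for v in row) + "\n")


def density_map(values_x, values_y, bins=0.5,
                x_label: str = "RMSD_bound",
                y_label: str = "RMSD_domains") -> DensityMap2D:
    """2D histogram of two per-frame measures; ``bins`` may be a bin width
    in the data units (default 0.5) or explicit (x_edges, y_edges)."""
    x = np.asarray(values_x, dtype=float)
    y = np.asarray(values_y, dtype=float)
    if len(x) != len(y):
        raise ValueError("value vectors must have equal length")
    if len(x) == 0:
        e = np.array([0.0, 1.0])
        z = np.zeros((1, 1))
        return DensityMap2D(e, e, z, z, x_label, y_label)
    if isinstance(bins, (int, float)):
        w = float(bins)
        x_edges = np.arange(np.floor(x.min() / w) * w, x.max() + w, w)
        y_edges = np.arange(np.floor(y.min() / w) * w, y.max() + w, w)
        if len(x_edges) < 2:
            x_edges = np.array([x.min(), x.min() + w])
        if len(y_edges) < 2:
            y_edges = np.array([y.min(), y.min() + w])
    else:
        x_edges, y_edges = map(np.asarray, bins)
    counts, x_edges, y_edges = np.histogram2d(x, y, bins=(x_edges, y_edges))
    return DensityMap2D(x_edges, y_edges, counts, counts / counts.sum(),
                        x_label, y_label)


@dataclass
class ContactProfile:
    """Per-ligand-residue contact with a receptor selection."""

    residues: np.ndarray  # 1-based ligand residue numbers
    in_contact: np.ndarray  # bool per ligand residue (contact with ANY)
    counts: np.ndarray  # number of receptor residues contacted
    cutoff: float = 4.5

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("residue\tin_contact\tn_contacts\n")
            for r, c, n in zip(self.residues, self.in_contact, self.counts):
                fh.write(f"{r}\t{int(c)}\t{n}\n")


def _residue_atoms(chain: CGChain):
    """Represented-atom set per residue: Cα, Cβ and side-chain center
    (glycine contributes only its Cα)."""
    atoms, owner = [], []
    for i, aa in enumerate(chain.sequence):
        atoms.append(chain.ca[i]); owner.append(i)
        if aa != "G":
            atoms.append(chain.cb[i]); owner.append(i)
            atoms.append(chain.sc[i]); owner.append(i)
    return np.asarray(atoms), np.asarray(owner)


def contact_profile(
    state: SystemState,
    ligand_sel,
    receptor_sel,
    cutoff: float = 4.5,
) -> ContactProfile:
    """Two residues are in contact when any pair of their represented atoms
    (Cα, Cβ, side-chain center) is closer than ``cutoff``; the profile marks,
    per ligand residue, contact with ANY residue of the receptor selection."""
    by_id = {c.chain_id: c for c in state.chains}

    def gather(sel):
        atoms, owners, keys = [], [], []
        for chain_id, spans in parse_selection(sel):
            chain = by_id[chain_id]
            a, o = _residue_atoms(chain)
            for lo, hi in spans:
                m = (o >= lo - 1) & (o <= hi - 1)
                atoms.append(a[m])
                owners.append(o[m])
                keys.extend((chain_id, r) for r in range(lo, hi + 1))
        return np.vstack(atoms), np.concatenate(owners), keys

    _, _, lig_keys = gather(ligand_sel)
    # receptor atoms grouped by selected residue
    rec_atoms_list, rec_groups = [], []
    gid = 0
    for chain_id, spans in parse_selection(receptor_sel):
        chain = by_id[chain_id]
        a, o = _residue_atoms(chain)
        for lo, hi in spans:
            for r in range(lo - 1, hi):
                m = o == r
                rec_atoms_list.append(a[m])
                rec_groups.append(np.full(int(m.sum()), gid))
                gid += 1
    rec_atoms = np.vstack(rec_atoms_list)
    rec_groups = np.concatenate(rec_groups)

    lig_ids = sorted(set(map(tuple, [(k[0], k[1]) for k in lig_keys])),
                     key=lambda k: (k[0], k[1]))
    in_contact = np.zeros(len(lig_ids), dtype=bool)
    counts = np.zeros(len(lig_ids), dtype=int)
    for li, (chain_id, resnum) in enumerate(lig_ids):
        chain = by_id[chain_id]
        a, o = _residue_atoms(chain)
        mine = a[o == resnum - 1]
        d = cdist(mine, rec_atoms).min(axis=0)
        touched = np.unique(rec_groups[d < cutoff])
        counts[li] = len(touched)
        in_contact[li] = counts[li] > 0
    return ContactProfile(
        residues=np.array([r for _, r in lig_ids]),
        in_contact=in_contact,
        counts=counts,
        cutoff=cutoff,
    )


def radius_of_gyration(coords: np.ndarray) -> float:
    """Root-mean-square distance of the (unweighted) points from their
    centroid."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or len(coords) == 0:
        raise ValueError("need a non-empty (n, 3) coordinate array")
    d = coords - coords.mean(axis=0)
    return float(np.sqrt((d * d).sum() / len(coords)))


# ---------------------------------------------------------------------------
# kernel density estimation
# ---------------------------------------------------------------------------


def silverman_bandwidth(samples: np.ndarray) -> float:
    """Silverman's rule of thumb; falls back to 1.0 for degenerate samples."""
    x = np.asarray(samples, dtype=float)
    sd = x.std(ddof=1) if len(x) > 1 else 0.0
    if sd <= 0:
        return 1.0
    return float(1.06 * sd * len(x) ** (-1 / 5))


@dataclass
class KDEConfig:
    grid: np.ndarray
    h: float | None = None  # None: Silverman's rule on the input sample

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.h is not None and self.h <= 0:
            raise ValueError("bandwidth h must be positive")
        if not np.all(np.isfinite(self.grid)) or np.any(np.diff(self.grid) < 0):
            raise ValueError("grid must be finite and sorted")


@dataclass
class KDEResult:
    grid: np.ndarray
    density: np.ndarray
    h: float  # bandwidth actually used (echoed metadata)


def kde_estimate(samples: np.ndarray, config: KDEConfig) -> KDEResult:
    """Gaussian kernel density estimate

        f̂_h(x) = 1/(N h) Σ_i K((x - x_i) / h)

    with K the standard normal density (mean 0, variance 1)."""
    x = np.asarray(samples, dtype=float)
    if len(x) == 0:
        raise ValueError("need at least one sample")
    h = config.h if config.h is not None else silverman_bandwidth(x)
    u = (config.grid[:, None] - x[None, :]) / h
    k = np.exp(-0.5 * u * u) / np.sqrt(2.0 * np.pi)
    density = k.sum(axis=1) / (len(x) * h)
    return KDEResult(config.grid, density, h)


def distance_series(
    traj: Trajectory,
    site_a: tuple[str, int],
    site_b: tuple[str, int],
    frames: list[Frame] | None = None,
) -> np.ndarray:
    """Per-frame Cα–Cα distance between two residues given as
    (chain_id, 1-based residue number); feedable to kde_estimate."""
    frames = traj.frames if frames is None else frames
    out = np.empty(len(frames))
    for k, f in enumerate(frames):
        s = frame_structure(traj, f)
        for cid, res in (site_a, site_b):
            if cid not in s or not (1 <= res <= len(s[cid])):
                raise KeyError(f"residue {cid}:{res} not present")
        pa = s[site_a[0]][site_a[1] - 1]
        pb = s[site_b[0]][site_b[1] - 1]
        out[k] = np.linalg.norm(pa - pb)
    return out


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


@dataclass
class ClusterResult:
    labels: np.ndarray  # cluster id per frame, 0-based, size-ordered
    sizes: np.ndarray  # frames per cluster
    medoids: np.ndarray  # frame index of each cluster's medoid
    cutoff: float = 1.5
    method: str = "single"
    rmsd_matrix: np.ndarray = None

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)


def _frame_coords(frames) -> list[np.ndarray]:
    out = []
    for f in frames:
        if isinstance(f, Frame):
            out.append(np.vstack(f.coords))
        else:
            out.append(np.asarray(f, dtype=float))
    return out


def pairwise_rmsd(frames) -> np.ndarray:
    """Symmetric matrix of pairwise Cα RMSD after optimal superposition."""
    coords = _frame_coords(frames)
    n = len(coords)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = superpose(coords[i], coords[j]).rmsd
    return m


def cluster_frames(
    frames, cutoff: float = 1.5, method: str = "single"
) -> ClusterResult:
    """Agglomerative linkage clustering on the pairwise RMSD matrix, cut at
    ``cutoff`` (Å).  ``method`` is the linkage flavour; single linkage is
    the default.  Clusters are numbered by decreasing size; each cluster's
    representative is its medoid (minimum mean RMSD to members)."""
    coords = _frame_coords(frames)
    n = len(coords)
    if n == 0:
        raise ValueError("need at least one frame")
    if n == 1:
        return ClusterResult(np.zeros(1, dtype=int), np.ones(1, dtype=int),
                             np.zeros(1, dtype=int), cutoff, method,
                             np.zeros((1, 1)))
    m = pairwise_rmsd(coords)
    z = linkage(squareform(m, checks=False), method=method)
    raw = fcluster(z, t=cutoff, criterion="distance")  # 1-based
    ids, counts = np.unique(raw, return_counts=True)
    order = np.argsort(-counts, kind="stable")
    remap = {int(ids[o]): rank for rank, o in enumerate(order)}
    labels = np.array([remap[int(r)] for r in raw])
    sizes = counts[order]
    medoids = np.empty(len(ids), dtype=int)
    for c in range(len(ids)):
        members = np.nonzero(labels == c)[0]
        sub = m[np.ix_(members, members)]
        medoids[c] = members[int(np.argmin(sub.mean(axis=1)))]
    return ClusterResult(labels, sizes, medoids, cutoff, method, m)
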