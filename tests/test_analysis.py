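"""RMSD machinery, ensemble measures, KDE and clustering, checked against
independent oracles and planted ground truth."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation
from scipy.stats import chi2, gaussian_kde

import cgdock as cg
from cgdock.analysis import (
    ClusterResult,
    KDEConfig,
    RMSDSpec,
    cluster_frames,
    contact_profile,
    density_map,
    distance_series,
    frame_structure,
    kde_estimate,
    parse_selection,
    radius_of_gyration,
    rmsd_metric,
    silverman_bandwidth,
    superpose,
    transition_curve,
)
from cgdock.fixtures import (
    PlantedTrajectorySpec,
    make_ideal_helix,
    make_planted_trajectory,
    make_random_coil,
    make_two_domain_receptor,
)
from cgdock.representation import SystemState
from tests.test_energy import _chain_from_coords


def _random_rigid(rng):
    rot = Rotation.random(rng=rng).as_matrix()
    return rot, rng.uniform(-20, 20, size=3)


class TestSuperpose:
    def test_identical_sets_give_zero_and_identity(self):
        xyz, _ = make_random_coil(15, seed=1)
        res = superpose(xyz, xyz)
        assert res.rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(res.rotation, np.eye(3), atol=1e-8)

    def test_recovers_a_rigid_transform_exactly(self, rng):
        xyz, _ = make_random_coil(20, seed=2)
        rot, t = _random_rigid(rng)
        res = superpose(xyz @ rot.T + t, xyz)
        assert res.rmsd < 1e-6

    def test_never_uses_a_reflection(self, rng):
        xyz, _ = make_random_coil(12, seed=3)
        mirrored = xyz * np.array([-1.0, 1.0, 1.0])
        res = superpose(mirrored, xyz)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)
        assert res.rmsd > 0.1

    def test_matches_scipy_align_vectors(self, rng):
        """Independent oracle: scipy's weighted Wahba solver on the same
        centred point sets."""
        for seed in range(3):
            a, _ = make_random_coil(10, seed=40 + seed)
            b = a + rng.normal(scale=1.0, size=a.shape)
            res = superpose(a, b)
            rot, rssd = Rotation.align_vectors(b - b.mean(0), a - a.mean(0))
            assert res.rmsd == pytest.approx(rssd / math.sqrt(len(a)),
                                             rel=1e-6)

    def test_degenerate_input_falls_back_to_translation(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        res = superpose(line + 5.0, line)
        assert res.translation_only
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)


class TestRMSDMetric:
    @pytest.fixture()
    def receptor(self):
        xyz, seq, ann = make_two_domain_receptor(30, 5, 30, seed=3)
        return xyz, seq, ann

    def test_self_rmsd_is_zero_for_all_specs(self, receptor):
        xyz, seq, ann = receptor
        s = {"A": xyz}
        (d1s, d1e), (d2s, d2e) = ann["domains"]
        specs = [
            RMSDSpec(f"A:1-{len(seq)}"),
            RMSDSpec(f"A:{d1s + 1}-{d1e + 1},{d2s + 1}-{d2e + 1}"),
            RMSDSpec(f"A:{d1s + 1}-{d1e + 1}", superpose_on=f"A:1-{len(seq)}"),
        ]
        for spec in specs:
            assert rmsd_metric(s, s, spec) == pytest.approx(0.0, abs=1e-10)

    def test_domain_rotation_matches_two_step_oracle(self, receptor, rng):
        """One domain rotated about the linker: the domains-only RMSD equals
        an independently scripted superpose-then-measure computation."""
        xyz, seq, ann = receptor
        (d1s, d1e), (d2s, d2e) = ann["domains"]
        moved = xyz.copy()
        pivot = xyz[d2s]
        rot = Rotation.from_rotvec(np.deg2rad(30) * np.array([0, 0, 1.0]))
        moved[d2s:] = (moved[d2s:] - pivot) @ rot.as_matrix().T + pivot
        sel = f"A:{d1s + 1}-{d1e + 1},{d2s + 1}-{d2e + 1}"
        got = rmsd_metric({"A": moved}, {"A": xyz}, RMSDSpec(sel))

        idx = np.r_[d1s:d1e + 1, d2s:d2e + 1]
        a, b = moved[idx], xyz[idx]
        rot2, rssd = Rotation.align_vectors(b - b.mean(0), a - a.mean(0))
        expected = rssd / math.sqrt(len(idx))
        assert got == pytest.approx(expected, rel=1e-6)

    def test_missing_selection_named_in_error(self, receptor):
        xyz, seq, _ = receptor
        with pytest.raises(KeyError, match="B"):
            rmsd_metric({"A": xyz}, {"A": xyz}, RMSDSpec("B:1-10"))

    def test_selection_parser(self):
        assert parse_selection("A:3-33") == [("A", [(3, 33)])]
        assert parse_selection("A:1-10,20-30;P:1-8") == [
            ("A", [(1, 10), (20, 30)]), ("P", [(1, 8)])
        ]
        with pytest.raises(ValueError):
            parse_selection("A:10-3")


class TestTransitionCurve:
    def test_planted_mixture_fractions_recovered(self):
        """30% of frames at ~0 Å and 70% at ~9 Å per temperature: the
        near-native fraction at the 6 Å threshold is 0.30 up to counting
        error."""
        ref, seq = make_random_coil(20, seed=50)
        far = ref + np.array([9.0 * math.sqrt(20 / 20), 0, 0])
        far = ref + 9.0 * np.eye(3)[0]  # rigid shift: RMSD 9 pre-fit...
        # make 'far' genuinely deformed so superposition cannot undo it
        rng = np.random.default_rng(0)
        far = ref + rng.normal(scale=9.0, size=ref.shape)
        n = 400
        spec = PlantedTrajectorySpec(
            conformers=[ref, far],
            weights={1.5: [0.3, 0.7], 2.5: [0.3, 0.7]},
            n_frames=n, jitter_sigma=0.0, seed=7, sequence=seq,
        )
        traj = make_planted_trajectory(spec)
        curve = transition_curve(traj, {"A": ref}, RMSDSpec("A:1-20"),
                                 threshold=6.0, second_half=False)
        assert np.array_equal(curve.temperatures, [1.5, 2.5])
        sigma = math.sqrt(0.3 * 0.7 / n)
        for frac in curve.fractions:
            assert abs(frac - 0.3) < 4 * sigma

    def test_all_frames_native_gives_ones(self):
        ref, seq = make_random_coil(10, seed=51)
        spec = PlantedTrajectorySpec(conformers=[ref],
                                     weights={1.5: [1.0]}, n_frames=20,
                                     seed=1, sequence=seq)
        traj = make_planted_trajectory(spec)
        curve = transition_curve(traj, {"A": ref}, RMSDSpec("A:1-10"),
                                 second_half=False)
        assert np.all(curve.fractions == 1.0)

    def test_all_frames_far_gives_zeros(self):
        ref, seq = make_random_coil(10, seed=52)
        rng = np.random.default_rng(1)
        far = ref + rng.normal(scale=12.0, size=ref.shape)
        spec = PlantedTrajectorySpec(conformers=[far],
                                     weights={1.5: [1.0]}, n_frames=20,
                                     seed=1, sequence=seq)
        traj = make_planted_trajectory(spec)
        curve = transition_curve(traj, {"A": ref}, RMSDSpec("A:1-10"),
                                 second_half=False)
        assert np.all(curve.fractions == 0.0)


class TestDensityMap:
    def test_single_point_occupies_one_cell(self):
        m = density_map([3.2], [4.7], bins=0.5)
        assert m.counts.sum() == 1
        assert (m.counts == 1).sum() == 1

    def test_counts_are_conserved(self, rng):
        x = rng.uniform(0, 10, size=500)
        y = rng.uniform(0, 10, size=500)
        m = density_map(x, y, bins=0.5)
        assert m.counts.sum() == 500
        assert m.density.sum() == pytest.approx(1.0)

    def test_marginals_equal_1d_histograms(self, rng):
        x = rng.uniform(0, 8, size=300)
        y = rng.uniform(0, 8, size=300)
        m = density_map(x, y, bins=1.0)
        hx, _ = np.histogram(x, bins=m.x_edges)
        hy, _ = np.histogram(y, bins=m.y_edges)
        assert np.array_equal(m.counts.sum(axis=1), hx)
        assert np.array_equal(m.counts.sum(axis=0), hy)

    def test_uniform_values_pass_chi_square(self):
        rng = np.random.default_rng(99)
        n = 4000
        x = rng.uniform(0, 10, size=n)
        y = rng.uniform(0, 10, size=n)
        m = density_map(x, y, bins=(np.linspace(0, 10, 6),
                                    np.linspace(0, 10, 6)))
        expected = n / 25
        stat = ((m.counts - expected) ** 2 / expected).sum()
        assert stat < chi2.ppf(0.999, df=24)

    def test_empty_input_gives_empty_map(self):
        m = density_map([], [])
        assert m.counts.sum() == 0


class TestContactProfile:
    def _two_residue_system(self, gap):
        xyz1 = np.array([[0.0, 0, 0], [3.8, 0, 0], [7.6, 0, 0]])
        xyz2 = xyz1 + np.array([0.0, gap, 0.0])
        c1 = _chain_from_coords(xyz1, "AAA", "A")
        c2 = _chain_from_coords(xyz2, "AAA", "P")
        d = np.linalg.norm(c1.sc[1] - c2.sc[1])
        return SystemState(receptor=[c1], ligand=c2), d

    def test_threshold_straddle(self):
        """A pair just under the cutoff is a contact; just over is not."""
        for target, expect in ((4.4, True), (4.6, False)):
            xyz1 = np.array([[0.0, 0, 0], [3.8, 0, 0], [7.6, 0, 0]])
            c1 = _chain_from_coords(xyz1, "GGG", "A")
            c2 = _chain_from_coords(xyz1 + np.array([0.0, target, 0.0]),
                                    "GGG", "P")
            state = SystemState(receptor=[c1], ligand=c2)
            prof = contact_profile(state, "P:2-2", "A:1-3", cutoff=4.5)
            assert bool(prof.in_contact[0]) is expect

    def test_distant_ligand_has_empty_profile(self):
        state, _ = self._two_residue_system(50.0)
        prof = contact_profile(state, "P:1-3", "A:1-3", cutoff=4.5)
        assert not prof.in_contact.any()
        assert prof.counts.sum() == 0

    def test_matches_brute_force_over_all_atom_pairs(self):
        """O(n²) oracle: residue pair in contact iff min over the
        represented-atom pairs is below the cutoff."""
        xyz1, seq1 = make_random_coil(10, seed=60)
        xyz2, seq2 = make_random_coil(6, seed=61)
        c1 = _chain_from_coords(xyz1, seq1, "A")
        c2 = _chain_from_coords(xyz2 + np.array([4.0, 1.0, 0.0]), seq2, "P")
        state = SystemState(receptor=[c1], ligand=c2)
        prof = contact_profile(state, "P:1-6", "A:1-10", cutoff=4.5)

        def atoms(chain, i):
            out = [chain.ca[i]]
            if chain.sequence[i] != "G":
                out += [chain.cb[i], chain.sc[i]]
            return out

        for li in range(6):
            touched = 0
            for ri in range(10):
                dmin = min(
                    np.linalg.norm(p - q)
                    for p in atoms(c2, li)
                    for q in atoms(c1, ri)
                )
                touched += dmin < 4.5
            assert prof.counts[li] == touched
            assert prof.in_contact[li] == (touched > 0)

    def test_monotone_in_cutoff(self):
        xyz1, seq1 = make_random_coil(10, seed=62)
        xyz2, seq2 = make_random_coil(6, seed=63)
        c1 = _chain_from_coords(xyz1, seq1, "A")
        c2 = _chain_from_coords(xyz2 + np.array([3.0, 0.0, 0.0]), seq2, "P")
        state = SystemState(receptor=[c1], ligand=c2)
        p40 = contact_profile(state, "P:1-6", "A:1-10", cutoff=4.0)
        p45 = contact_profile(state, "P:1-6", "A:1-10", cutoff=4.5)
        assert np.all(p45.in_contact >= p40.in_contact)


class TestRadiusOfGyration:
    def test_single_point_is_zero(self):
        assert radius_of_gyration([[1.0, 2.0, 3.0]]) == 0.0

    def test_two_points_give_half_the_separation(self):
        assert radius_of_gyration([[0.0, 0, 0], [10.0, 0, 0]]) == pytest.approx(5.0)

    def test_matches_direct_formula(self, rng):
        pts = rng.normal(size=(50, 3)) * 4
        expected = math.sqrt(
            np.mean(np.linalg.norm(pts - pts.mean(axis=0), axis=1) ** 2))
        assert radius_of_gyration(pts) == pytest.approx(expected, rel=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            radius_of_gyration(np.empty((0, 3)))


class TestKDE:
    def test_single_sample_peak_height(self):
        h = 0.7
        out = kde_estimate([2.0], KDEConfig(grid=[2.0], h=h))
        assert out.density[0] == pytest.approx(1 / (h * math.sqrt(2 * math.pi)))

    def test_integrates_to_one(self, rng):
        x = rng.normal(size=40) * 2 + 5
        grid = np.linspace(-20, 30, 4001)
        out = kde_estimate(x, KDEConfig(grid=grid, h=0.8))
        integral = np.trapezoid(out.density, grid)
        assert integral == pytest.approx(1.0, abs=1e-3)

    def test_symmetric_samples_give_symmetric_density(self):
        grid = np.linspace(-5, 5, 101)
        out = kde_estimate([-1.7, 1.7], KDEConfig(grid=grid, h=0.5))
        assert np.allclose(out.density, out.density[::-1], atol=1e-15)

    def test_matches_scipy_gaussian_kde(self, rng):
        """Independent oracle: scipy's estimator at the same bandwidth."""
        x = rng.normal(size=60)
        grid = np.linspace(-4, 4, 201)
        h = 0.5
        ours = kde_estimate(x, KDEConfig(grid=grid, h=h))
        ref = gaussian_kde(x, bw_method=h / x.std(ddof=1))
        assert np.allclose(ours.density, ref(grid), rtol=1e-8, atol=1e-10)

    def test_default_bandwidth_is_silverman_and_echoed(self, rng):
        x = rng.normal(size=30)
        out = kde_estimate(x, KDEConfig(grid=np.linspace(-3, 3, 11)))
        assert out.h == pytest.approx(silverman_bandwidth(x))

    def test_invalid_bandwidth_rejected(self):
        with pytest.raises(ValueError):
            KDEConfig(grid=[0.0], h=-1.0)


class TestDistanceSeries:
    def test_static_trajectory_gives_constant_series(self):
        ref, seq = make_random_coil(12, seed=70)
        spec = PlantedTrajectorySpec(conformers=[ref], weights={1.5: [1.0]},
                                     n_frames=8, seed=0, sequence=seq)
        traj = make_planted_trajectory(spec)
        series = distance_series(traj, ("A", 2), ("A", 10))
        assert len(series) == 8
        assert np.allclose(series, np.linalg.norm(ref[1] - ref[9]))

    def test_two_state_trajectory_gives_bimodal_kde(self):
        """Planted conformers at two distinct end-to-end distances show up
        as two KDE modes near the planted values."""
        ref, seq = make_random_coil(10, seed=71)
        stretched = ref.copy()
        stretched[-1] += (stretched[-1] - stretched[0]) * 2.0
        spec = PlantedTrajectorySpec(conformers=[ref, stretched],
                                     weights={1.5: [0.5, 0.5]},
                                     n_frames=200, seed=3, sequence=seq)
        traj = make_planted_trajectory(spec)
        series = distance_series(traj, ("A", 1), ("A", 10))
        d1 = np.linalg.norm(ref[0] - ref[9])
        d2 = np.linalg.norm(stretched[0] - stretched[9])
        h = 0.5
        grid = np.linspace(min(d1, d2) - 5, max(d1, d2) + 5, 400)
        out = kde_estimate(series, KDEConfig(grid=grid, h=h))
        for mode in (d1, d2):
            i = np.argmin(np.abs(grid - mode))
            region = out.density[max(0, i - 20):i + 20]
            assert out.density[i] > 0.1 * out.density.max()
            assert region.max() >= out.density[i]

    def test_missing_residue_rejected(self):
        ref, seq = make_random_coil(5, seed=72)
        spec = PlantedTrajectorySpec(conformers=[ref], weights={1.5: [1.0]},
                                     n_frames=2, seed=0, sequence=seq)
        traj = make_planted_trajectory(spec)
        with pytest.raises(KeyError):
            distance_series(traj, ("A", 1), ("A", 99))


class TestClustering:
    def test_identical_frames_form_one_cluster(self):
        xyz, _ = make_random_coil(10, seed=80)
        res = cluster_frames([xyz] * 6, cutoff=1.5)
        assert res.n_clusters == 1
        assert res.sizes[0] == 6

    def test_two_planted_conformers_found_at_1p5A_cutoff(self):
        """Two conformer families (intra ~0.5 Å jitter, inter ~8 Å) split
        into exactly two clusters with correct memberships."""
        rng = np.random.default_rng(4)
        a, _ = make_random_coil(15, seed=81)
        b = a + rng.normal(scale=8.0, size=a.shape)
        frames, truth = [], []
        for i in range(20):
            src = a if i % 2 == 0 else b
            frames.append(src + rng.normal(scale=0.5 / math.sqrt(3),
                                           size=src.shape))
            truth.append(i % 2)
        res = cluster_frames(frames, cutoff=1.5)
        assert res.n_clusters == 2
        lab = res.labels
        truth = np.array(truth)
        same = (lab == lab[0])
        assert np.array_equal(same, truth == truth[0])

    def test_large_cutoff_merges_everything(self):
        rng = np.random.default_rng(5)
        frames = [rng.normal(size=(8, 3)) * 3 for _ in range(5)]
        res = cluster_frames(frames, cutoff=1e6)
        assert res.n_clusters == 1

    def test_tiny_cutoff_gives_singletons(self):
        rng = np.random.default_rng(6)
        frames = [rng.normal(size=(8, 3)) * 3 for _ in range(5)]
        res = cluster_frames(frames, cutoff=1e-6)
        assert res.n_clusters == 5

    def test_medoid_minimises_mean_rmsd(self):
        rng = np.random.default_rng(7)
        base, _ = make_random_coil(10, seed=82)
        frames = [base + rng.normal(scale=0.3, size=base.shape)
                  for _ in range(7)]
        res = cluster_frames(frames, cutoff=1e6)
        means = res.rmsd_matrix.mean(axis=1)
        assert res.medoids[0] == np.argmin(means)


class TestTSVExports:
    def test_tables_written_with_expected_shapes(self, tmp_path, rng):
        x = rng.uniform(0, 8, 50)
        y = rng.uniform(0, 8, 50)
        m = density_map(x, y, bins=1.0)
        m.to_tsv(tmp_path / "map.tsv")
        lines = (tmp_path / "map.tsv").read_text().strip().split("\n")
        assert len(lines) == len(m.x_edges)  # header + one row per x bin

        ref, seq = make_random_coil(10, seed=55)
        spec = PlantedTrajectorySpec(conformers=[ref], weights={1.5: [1.0]},
                                     n_frames=6, seed=0, sequence=seq)
        traj = make_planted_trajectory(spec)
        curve = transition_curve(traj, {"A": ref}, RMSDSpec("A:1-10"),
                                 second_half=False)
        curve.to_tsv(tmp_path / "curve.tsv")
        body = (tmp_path / "curve.tsv").read_text().strip().split("\n")
        assert body[0] == "temperature\tfraction\tn_frames"
        assert len(body) == 2
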