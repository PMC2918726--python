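import numpy as np
import pytest

from ensmap.probe_mapping import (
    COULOMB_K,
    MappingConfig,
    Pose,
    build_consensus_sites,
    build_energy_grids,
    cluster_poses,
    lorentz_berthelot,
    map_structure,
    minimize_pose,
    minimize_poses,
    pose_energy,
    rotation_set,
    sample_poses,
)
from ensmap.probes import ProbeType, get_probe
from ensmap.structure_io import Structure

from conftest import make_atom

IDENTITY_Q = np.array([1.0, 0.0, 0.0, 0.0])


def single_atom_probe(cls="C3", charge=0.0):
    return ProbeType(
        name="test-atom",
        code="TST",
        atom_names=("C1",),
        elements=("C",),
        coords=np.zeros((1, 3)),
        atom_classes=(cls,),
        charges=np.array([charge]),
        net_charge=charge,
    )


def single_bead_receptor(cls="SCA", charge=0.0):
    return Structure(0, [make_atom(1, [0.0, 0.0, 0.0], atom_class=cls, charge=charge)])


def place(probe, xyz, energy=0.0):
    return Pose(
        probe=probe,
        rotation=IDENTITY_Q,
        translation=np.asarray(xyz, dtype=float),
        energy=energy,
    )


class TestDirectEnergy:
    def test_lj_zero_at_sigma(self):
        probe = single_atom_probe()
        rec = single_bead_receptor()
        sigma, _ = lorentz_berthelot("C3", "SCA")
        e = pose_energy(rec, place(probe, [sigma, 0, 0]), MappingConfig())
        assert abs(e) < 1e-9

    def test_lj_minimum_is_minus_epsilon(self):
        probe = single_atom_probe()
        rec = single_bead_receptor()
        sigma, eps = lorentz_berthelot("C3", "SCA")
        r_min = 2.0 ** (1.0 / 6.0) * sigma
        e = pose_energy(rec, place(probe, [r_min, 0, 0]), MappingConfig())
        assert abs(e + eps) < 1e-9

    def test_zero_beyond_cutoff(self):
        probe = single_atom_probe(charge=0.3)
        rec = single_bead_receptor(charge=0.45)
        cfg = MappingConfig()
        e = pose_energy(rec, place(probe, [cfg.nonbonded_cutoff + 0.1, 0, 0]), cfg)
        assert e == 0.0

    def test_clash_capped_per_pair(self):
        probe = single_atom_probe()
        rec = single_bead_receptor()
        cfg = MappingConfig()
        e = pose_energy(rec, place(probe, [0.8, 0, 0]), cfg)
        assert e == pytest.approx(cfg.clash_cap)

    def test_hand_summed_pairwise_terms(self):
        """3-atom probe vs 2-atom receptor: every pair summed by hand."""
        from ensmap._kernels import R_CLAMP

        probe = ProbeType(
            name="tri",
            code="TRI",
            atom_names=("C1", "C2", "O1"),
            elements=("C", "C", "O"),
            coords=np.array([[-1.0, 0, 0], [1.0, 0, 0], [0.0, 0, 0]]),
            atom_classes=("C3", "C2", "OH"),
            charges=np.array([0.1, 0.1, -0.2]),
            net_charge=0.0,
        )
        atoms = [
            make_atom(1, [0.0, 4.0, 0.0], atom_class="SCA", charge=0.0),
            make_atom(2, [2.0, 5.0, 1.0], atom_class="SCN", charge=0.45, residue_seq=2),
        ]
        rec = Structure(0, atoms)
        cfg = MappingConfig()
        pose = place(probe, [0.5, 0.5, 0.5])
        expected = 0.0
        for a in range(3):
            pa = probe.coords[a] + pose.translation
            qa = probe.charges[a]
            for r_atom in atoms:
                r = np.linalg.norm(pa - r_atom.coords)
                if r > cfg.nonbonded_cutoff:
                    continue
                sigma, eps = lorentz_berthelot(probe.atom_classes[a], r_atom.atom_class)
                s6 = (sigma / r) ** 6
                expected += min(4 * eps * (s6**2 - s6), cfg.clash_cap)
                expected += COULOMB_K / 4.0 * qa * r_atom.charge / max(r, R_CLAMP) ** 2
        assert pose_energy(rec, pose, cfg) == pytest.approx(expected, abs=1e-10)


class TestEnergyGrids:
    def test_grid_matches_direct_sum_at_random_points(self, random_receptor):
        """Trilinear interpolation vs direct pair sums for a single probe
        atom at random off-grid points."""
        cfg = MappingConfig()
        grid = build_energy_grids(random_receptor, cfg)
        rng = np.random.default_rng(11)
        probe = single_atom_probe("OH", charge=0.2)
        worst = 0.0
        n_checked = 0
        while n_checked < 50:
            xyz = rng.uniform(-6, 6, 3)
            direct = pose_energy(random_receptor, place(probe, xyz), cfg)
            if direct >= 0:  # representation is asserted for attractive placements
                continue
            n_checked += 1
            interp = grid.interpolate(6, xyz[None])[0] + 0.2 * grid.interpolate(None, xyz[None])[0]
            worst = max(worst, abs(direct - interp))
        assert worst < 1.0

    def test_empty_receptor_rejected(self):
        h = make_atom(1, [0, 0, 0], element="H", atom_class="H")
        with pytest.raises(ValueError, match="no heavy atoms"):
            build_energy_grids(Structure(0, [h]), MappingConfig())


class TestSampling:
    def test_single_attractive_atom_best_pose_exhaustive(self):
        """With one uncharged receptor bead, the best retained pose must
        sit at the grid point whose LJ energy is the global discrete
        minimum — verified by full enumeration in numpy."""
        rec = single_bead_receptor()
        probe = single_atom_probe()
        cfg = MappingConfig(rotation_count=3, poses_retained=10)
        grid = build_energy_grids(rec, cfg)
        poses = sample_poses(grid, probe, cfg)
        pts = grid.grid_points()
        sigma, eps = lorentz_berthelot("C3", "SCA")
        r = np.linalg.norm(pts, axis=1)
        with np.errstate(over="ignore", divide="ignore"):
            s6 = (sigma / np.maximum(r, 1e-6)) ** 6
            lj = np.minimum(4 * eps * (s6**2 - s6), cfg.clash_cap)
        lj[r > cfg.nonbonded_cutoff] = 0.0
        best_direct = pts[np.argmin(lj)]
        assert np.allclose(poses[0].translation, best_direct, atol=1e-9)

    def test_retained_count_caps_at_poses_retained(self, random_receptor):
        cfg = MappingConfig(rotation_count=5, poses_retained=200)
        grid = build_energy_grids(random_receptor, cfg)
        poses = sample_poses(grid, get_probe("ethane"), cfg)
        assert len(poses) == 200
        energies = [p.energy for p in poses]
        assert energies == sorted(energies)

    def test_fewer_candidates_than_retained_returns_all(self):
        rec = single_bead_receptor()
        probe = single_atom_probe()
        cfg = MappingConfig(rotation_count=1, poses_retained=10**9)
        grid = build_energy_grids(rec, cfg)
        poses = sample_poses(grid, probe, cfg)
        assert len(poses) == int(np.prod(grid.dims))

    def test_retention_correctness_no_better_pose_discarded(self):
        """Exhaustive enumeration oracle on a small grid: no discarded
        candidate may have lower energy than the worst retained pose."""
        rec = single_bead_receptor()
        probe = single_atom_probe()
        cfg = MappingConfig(rotation_count=2, poses_retained=50)
        grid = build_energy_grids(rec, cfg)
        poses = sample_poses(grid, probe, cfg)
        worst_retained = poses[-1].energy
        pts = grid.grid_points()
        # single-atom probe: energy is rotation-independent; enumerate all
        energies = grid.interpolate(0, pts)
        retained_keys = {tuple(np.round(p.translation, 6)) for p in poses}
        for pt, e in zip(pts, energies):
            if tuple(np.round(pt, 6)) in retained_keys:
                continue
            assert e >= worst_retained - 1e-9

    def test_shell_pruning_preserves_retained_set(self, random_receptor):
        cfg_full = MappingConfig(rotation_count=4, poses_retained=300)
        cfg_shell = MappingConfig(
            rotation_count=4, poses_retained=300, sample_shell=(1.5, 7.0)
        )
        grid = build_energy_grids(random_receptor, cfg_full)
        full = sample_poses(grid, get_probe("ethanol"), cfg_full)
        shell = sample_poses(grid, get_probe("ethanol"), cfg_shell)
        for a, b in zip(full, shell):
            assert a.energy == pytest.approx(b.energy, abs=1e-12)
            assert np.allclose(a.translation, b.translation)

    def test_rotation_set_deterministic_and_unit(self):
        a = rotation_set(64, seed=5)
        b = rotation_set(64, seed=5)
        c = rotation_set(64, seed=6)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)
        assert np.allclose(np.linalg.norm(a, axis=1), 1.0, atol=1e-12)


class TestMinimization:
    def test_descent_contract(self, random_receptor):
        cfg = MappingConfig(rotation_count=4, poses_retained=100)
        grid = build_energy_grids(random_receptor, cfg)
        poses = sample_poses(grid, get_probe("ethanol"), cfg)
        minimized = minimize_poses(random_receptor, poses, cfg)
        for before, after in zip(poses, minimized):
            start = pose_energy(random_receptor, before, cfg)
            assert after.energy <= start + 1e-9
            assert after.energy == pytest.approx(
                pose_energy(random_receptor, after, cfg), abs=1e-8
            )

    def test_near_stationary_pose_stays(self):
        probe = single_atom_probe()
        rec = single_bead_receptor()
        cfg = MappingConfig()
        sigma, eps = lorentz_berthelot("C3", "SCA")
        r_min = 2.0 ** (1.0 / 6.0) * sigma
        pose = place(probe, [r_min, 0, 0], energy=-eps)
        out = minimize_pose(rec, pose, cfg)
        assert -eps - 0.1 < out.energy <= -eps + 1e-12

    def test_converges_to_analytic_lj_minimum(self):
        probe = single_atom_probe()
        rec = single_bead_receptor()
        cfg = MappingConfig(minimize_max_iter=200)
        sigma, eps = lorentz_berthelot("C3", "SCA")
        r_min = 2.0 ** (1.0 / 6.0) * sigma
        pose = place(probe, [r_min + 0.5, 0, 0])
        out = minimize_pose(rec, pose, cfg)
        assert abs(np.linalg.norm(out.translation) - r_min) < 0.1
        assert out.energy == pytest.approx(-eps, abs=1e-3)


class TestPoseClustering:
    def greedy_reference(self, poses, cutoff, keep):
        """Independently coded greedy reference (quadratic, list-based)."""
        order = sorted(range(len(poses)), key=lambda i: (poses[i].energy, i))
        coords = {i: poses[i].coords() for i in range(len(poses))}
        unassigned = list(order)
        clusters = []
        while unassigned:
            seed = unassigned[0]
            members = []
            for i in list(unassigned):
                diff = coords[i] - coords[seed]
                rmsd = float(np.sqrt((diff**2).sum() / diff.shape[0]))
                if rmsd <= cutoff:
                    members.append(i)
            clusters.append((seed, members))
            unassigned = [i for i in unassigned if i not in members]
        scored = []
        for seed, members in clusters:
            mean_e = float(np.mean([poses[i].energy for i in members]))
            scored.append((mean_e, poses[seed].energy, seed, members))
        scored.sort()
        return scored[:keep]

    def test_identical_poses_single_cluster(self):
        probe = get_probe("ethane")
        poses = [place(probe, [5, 0, 0], energy=-2.0) for _ in range(4)]
        clusters = cluster_poses(poses, MappingConfig())
        assert len(clusters) == 1
        assert clusters[0].size == 4
        assert clusters[0].mean_energy == pytest.approx(-2.0)

    def test_two_separated_blobs(self):
        probe = get_probe("ethane")
        poses = [place(probe, [5 + 0.1 * i, 0, 0], energy=-3.0 + 0.01 * i) for i in range(3)]
        poses += [place(probe, [25 + 0.1 * i, 0, 0], energy=-1.0 + 0.01 * i) for i in range(4)]
        clusters = cluster_poses(poses, MappingConfig())
        assert sorted(c.size for c in clusters) == [3, 4]
        for c in clusters:
            xs = [p.translation[0] for p in c.members]
            assert max(xs) - min(xs) < 1.0

    def test_matches_independent_greedy_on_random_instances(self):
        rng = np.random.default_rng(13)
        probe = get_probe("ethanol")
        cfg = MappingConfig(pose_cluster_cutoff=3.0, clusters_per_probe=6)
        for trial in range(100):
            n = int(rng.integers(2, 31))
            poses = []
            for i in range(n):
                q = rng.normal(size=4)
                q /= np.linalg.norm(q)
                poses.append(
                    Pose(
                        probe=probe,
                        rotation=q,
                        translation=rng.uniform(-8, 8, 3),
                        energy=float(np.round(rng.uniform(-10, 0), 3)),
                    )
                )
            ours = cluster_poses(poses, cfg)
            ref = self.greedy_reference(poses, cfg.pose_cluster_cutoff, cfg.clusters_per_probe)
            assert len(ours) == len(ref)
            for c, (mean_e, _, seed, members) in zip(ours, ref):
                assert c.mean_energy == pytest.approx(mean_e, abs=1e-12)
                assert c.center is poses[seed]
                assert len(c.members) == len(members)

    def test_empty_input(self):
        assert cluster_poses([], MappingConfig()) == []


class TestConsensusSites:
    def _cluster_at(self, probe, xyz, mean_energy):
        from ensmap.probe_mapping import PoseCluster

        pose = place(probe, xyz, energy=mean_energy)
        return PoseCluster(probe=probe, members=[pose], center=pose, mean_energy=mean_energy)

    def test_single_cluster_single_site(self):
        site = build_consensus_sites(
            [self._cluster_at(get_probe("ethane"), [5, 0, 0], -2.0)], MappingConfig()
        )
        assert len(site) == 1
        assert site[0].rank == 1
        assert site[0].size == 1

    def test_size_ranking(self):
        probe_a, probe_b = get_probe("ethane"), get_probe("benzene")
        clusters = [self._cluster_at(probe_a, [0, 0, i * 0.5], -1.0) for i in range(5)]
        clusters += [self._cluster_at(probe_b, [30, 0, i * 0.5], -9.0) for i in range(3)]
        sites = build_consensus_sites(clusters, MappingConfig())
        assert [s.size for s in sites] == [5, 3]
        assert [s.rank for s in sites] == [1, 2]

    def test_truncated_to_top_cs(self):
        probe = get_probe("ethane")
        clusters = [self._cluster_at(probe, [20 * i, 0, 0], -1.0) for i in range(12)]
        sites = build_consensus_sites(clusters, MappingConfig(top_cs=10))
        assert len(sites) == 10
        assert [s.rank for s in sites] == list(range(1, 11))

    def test_every_cluster_in_exactly_one_site(self):
        rng = np.random.default_rng(3)
        probe = get_probe("ethanol")
        clusters = [
            self._cluster_at(probe, rng.uniform(-20, 20, 3), float(rng.uniform(-5, 0)))
            for _ in range(25)
        ]
        cfg = MappingConfig(top_cs=1000)
        sites = build_consensus_sites(clusters, cfg)
        seen = [c for s in sites for c in s.member_clusters]
        assert len(seen) == 25
        assert len(set(map(id, seen))) == 25
        sizes = [s.size for s in sites]
        assert sizes == sorted(sizes, reverse=True)


class TestMapStructure:
    @pytest.fixture(scope="class")
    def small_cfg(self):
        return MappingConfig(rotation_count=24, poses_retained=300, sample_shell=(2.0, 6.0))

    def test_deterministic(self, small_cfg, random_receptor):
        rec = random_receptor
        probes = [get_probe("ethanol"), get_probe("benzene")]
        a = map_structure(rec, small_cfg, probes=probes)
        b = map_structure(rec, small_cfg, probes=probes)
        assert len(a.consensus_sites) == len(b.consensus_sites)
        for sa, sb in zip(a.consensus_sites, b.consensus_sites):
            assert sa.size == sb.size
            assert np.array_equal(sa.center_of_mass, sb.center_of_mass)
            assert sa.mean_energy == sb.mean_energy
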