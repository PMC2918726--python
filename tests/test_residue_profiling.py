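import numpy as np
import pytest

from ensmap.probe_mapping import Pose
from ensmap.probes import ProbeType, get_probe
from ensmap.residue_profiling import (
    PlacedFragment,
    ProfilingConfig,
    aggregate_profiles,
    classify_orthosteric,
    count_contacts,
    group_sites,
    select_top_n,
)
from ensmap.structure_io import Structure

from conftest import make_atom

IDENTITY_Q = np.array([1.0, 0.0, 0.0, 0.0])


def residue(seq, xyz_list, chain="A"):
    return [
        make_atom(0, xyz, name="SCA", residue_seq=seq, chain_id=chain)
        for xyz in xyz_list
    ]


def probe_at(name, xyz, energy=-1.0):
    return Pose(
        probe=get_probe(name),
        rotation=IDENTITY_Q,
        translation=np.asarray(xyz, dtype=float),
        energy=energy,
    )


def single_atom_pose(xyz):
    probe = ProbeType(
        name="pt",
        code="PTT",
        atom_names=("C1",),
        elements=("C",),
        coords=np.zeros((1, 3)),
        atom_classes=("C3",),
        charges=np.zeros(1),
    )
    return Pose(probe=probe, rotation=IDENTITY_Q, translation=np.asarray(xyz, float), energy=0.0)


def brute_force_counts(structure, poses, radius):
    """Independent O(atoms x probe atoms) double loop."""
    counts = {key: 0 for key in structure.residue_index}
    for pose in poses:
        for pxyz in pose.coords():
            for atom in structure.atoms:
                if not atom.is_heavy:
                    continue
                if np.linalg.norm(atom.coords - pxyz) <= radius:
                    counts[atom.residue_key] += 1
    return counts


class TestCountContacts:
    def test_boundary_inclusive_at_4p9(self):
        s = Structure(0, residue(1, [[0.0, 0, 0]]))
        counts = count_contacts(s, [single_atom_pose([4.9, 0, 0])], ProfilingConfig())
        assert counts[("A", 1, "")] == 1

    def test_boundary_exclusive_at_5p1(self):
        s = Structure(0, residue(1, [[0.0, 0, 0]]))
        counts = count_contacts(s, [single_atom_pose([5.1, 0, 0])], ProfilingConfig())
        assert counts[("A", 1, "")] == 0

    def test_pair_counting_three_by_two(self):
        """3 probe atoms fully inside 5 A of a 2-atom residue -> 6 pairs."""
        s = Structure(0, residue(1, [[0.0, 0, 0], [1.5, 0, 0]]))
        pose = probe_at("ethanol", [0.7, 1.0, 0.0])  # 3 heavy atoms
        counts = count_contacts(s, [pose], ProfilingConfig())
        assert counts[("A", 1, "")] == 6

    def test_empty_pose_list_zero_map(self, random_receptor):
        counts = count_contacts(random_receptor, [], ProfilingConfig())
        assert set(counts) == set(random_receptor.residue_index)
        assert all(v == 0 for v in counts.values())

    def test_matches_brute_force_on_random_instances(self, random_receptor):
        rng = np.random.default_rng(21)
        cfg = ProfilingConfig()
        names = ["ethanol", "benzene", "urea", "ethane"]
        for trial in range(100):
            poses = [
                probe_at(names[int(rng.integers(len(names)))], rng.uniform(-8, 8, 3))
                for _ in range(int(rng.integers(1, 6)))
            ]
            ours = count_contacts(random_receptor, poses, cfg)
            ref = brute_force_counts(random_receptor, poses, cfg.contact_radius)
            assert ours == ref


class TestAggregate:
    def test_single_residue_holds_all(self):
        profiles = aggregate_profiles([{("A", 1, ""): 7}, {("A", 1, ""): 3}])
        assert profiles[0].percentage == 100.0
        assert profiles[0].raw_count == 10

    def test_equal_split(self):
        counts = {("A", i, ""): 5 for i in range(1, 5)}
        profiles = aggregate_profiles([counts])
        assert all(p.percentage == 25.0 for p in profiles)

    def test_sums_match_direct_recomputation(self):
        rng = np.random.default_rng(3)
        maps = []
        for _ in range(5):
            maps.append({("A", int(i), ""): int(rng.integers(0, 20)) for i in range(30)})
        profiles = aggregate_profiles(maps)
        assert sum(p.percentage for p in profiles) == pytest.approx(100.0, abs=1e-9)
        for p in profiles:
            assert p.raw_count == sum(m[p.residue_key] for m in maps)
        ranks = [p.raw_count for p in profiles]
        assert ranks == sorted(ranks, reverse=True)

    def test_zero_total_warns(self):
        with pytest.warns(UserWarning, match="no protein-probe contacts"):
            profiles = aggregate_profiles([{("A", 1, ""): 0}])
        assert profiles[0].percentage == 0.0

    def test_tie_broken_by_lower_residue_number(self):
        profiles = aggregate_profiles([{("A", 9, ""): 5, ("A", 2, ""): 5}])
        assert profiles[0].residue_key == ("A", 2, "")


class TestClassify:
    def _ligand(self, xyz):
        return Structure(
            0, [make_atom(1, xyz, name="C1", residue_seq=1, chain_id="L")]
        )

    def test_inside_radius_is_orthosteric(self):
        ref = Structure(0, residue(1, [[0.0, 0, 0]]) + residue(2, [[20.0, 0, 0]]))
        profiles = aggregate_profiles([{("A", 1, ""): 1, ("A", 2, ""): 1}])
        profiles = classify_orthosteric(profiles, ref, self._ligand([3.0, 0, 0]), ProfilingConfig())
        flags = {p.residue_key: p.orthosteric for p in profiles}
        assert flags[("A", 1, "")] is True
        assert flags[("A", 2, "")] is False

    def test_missing_ligand_warns_all_non_orthosteric(self):
        ref = Structure(0, residue(1, [[0.0, 0, 0]]))
        profiles = aggregate_profiles([{("A", 1, ""): 1}])
        with pytest.warns(UserWarning, match="no reference ligand"):
            profiles = classify_orthosteric(profiles, ref, None, ProfilingConfig())
        assert not profiles[0].orthosteric

    def test_recovers_generation_ground_truth(self):
        from ensmap.synthetic_data import (
            SyntheticSpec,
            generate_receptor,
            make_reference_ligand,
        )

        spec = SyntheticSpec()
        base, truth = generate_receptor(spec)
        ligand = make_reference_ligand(spec)
        counts = {key: 1 for key in base.residue_index}
        profiles = aggregate_profiles([counts])
        profiles = classify_orthosteric(profiles, base, ligand, ProfilingConfig())
        classified = {p.residue_key for p in profiles if p.orthosteric}
        assert classified == truth.orthosteric_residues


class TestTopN:
    def test_forty_of_hundred(self):
        counts = {("A", i, ""): 1000 - i for i in range(1, 101)}
        top = select_top_n(aggregate_profiles([counts]), ProfilingConfig(top_n=40))
        assert len(top) == 40
        assert top[0].residue_key == ("A", 1, "")

    def test_fewer_nonzero_than_top_n(self):
        counts = {("A", i, ""): (5 if i <= 12 else 0) for i in range(1, 30)}
        top = select_top_n(aggregate_profiles([counts]), ProfilingConfig(top_n=40))
        assert len(top) == 12

    def test_tie_at_boundary_keeps_lower_residue(self):
        counts = {("A", i, ""): 10 for i in range(1, 6)}
        counts[("A", 1, "")] = 20
        top = select_top_n(aggregate_profiles([counts]), ProfilingConfig(top_n=3))
        assert [p.residue_key[1] for p in top] == [1, 2, 3]


class TestGroupSites:
    def _profiles(self, keys, ref):
        counts = {key: 10 for key in keys}
        profiles = aggregate_profiles([counts])
        for p in profiles:
            p.orthosteric = False
        return profiles

    def test_two_clumps_two_sites(self):
        atoms = residue(1, [[0.0, 0, 0]]) + residue(2, [[3.0, 0, 0]])
        atoms += residue(10, [[30.0, 0, 0]]) + residue(11, [[33.0, 0, 0]])
        ref = Structure(0, atoms)
        profiles = self._profiles(ref.residue_index, ref)
        sites = group_sites(profiles, ref, [], ProfilingConfig())
        assert len(sites) == 2
        assert all(len(g.residues) == 2 for g in sites)

    def test_chain_linkage_single_site(self):
        atoms = []
        for i in range(6):
            atoms += residue(i + 1, [[4.0 * i, 0, 0]])
        ref = Structure(0, atoms)
        profiles = self._profiles(ref.residue_index, ref)
        sites = group_sites(profiles, ref, [], ProfilingConfig())
        assert len(sites) == 1
        assert len(sites[0].residues) == 6

    def test_orthosteric_residues_excluded(self):
        atoms = residue(1, [[0.0, 0, 0]]) + residue(2, [[3.0, 0, 0]])
        ref = Structure(0, atoms)
        profiles = self._profiles(ref.residue_index, ref)
        profiles[0].orthosteric = True
        sites = group_sites(profiles, ref, [], ProfilingConfig())
        grouped = {k for g in sites for k in g.residues}
        assert profiles[0].residue_key not in grouped

    def test_no_non_orthosteric_empty(self):
        atoms = residue(1, [[0.0, 0, 0]])
        ref = Structure(0, atoms)
        profiles = self._profiles(ref.residue_index, ref)
        profiles[0].orthosteric = True
        assert group_sites(profiles, ref, [], ProfilingConfig()) == []

    def test_site_ids_by_summed_percentage(self):
        atoms = residue(1, [[0.0, 0, 0]]) + residue(10, [[30.0, 0, 0]])
        ref = Structure(0, atoms)
        counts = {("A", 1, ""): 1, ("A", 10, ""): 9}
        profiles = aggregate_profiles([counts])
        for p in profiles:
            p.orthosteric = False
        sites = group_sites(profiles, ref, [], ProfilingConfig())
        assert sites[0].residues == [("A", 10, "")]
        assert sites[0].site_id == 1

    def test_poses_attached_by_contact(self):
        atoms = residue(1, [[0.0, 0, 0]]) + residue(10, [[40.0, 0, 0]])
        ref = Structure(0, atoms)
        profiles = self._profiles(ref.residue_index, ref)
        poses = [single_atom_pose([2.0, 0, 0]), single_atom_pose([60.0, 0, 0])]
        sites = group_sites(profiles, ref, poses, ProfilingConfig())
        by_res = {g.residues[0]: g for g in sites}
        assert len(by_res[("A", 1, "")].member_probes) == 1
        assert len(by_res[("A", 10, "")].member_probes) == 0


class TestPlacedFragment:
    def test_groups_hetatm_residues(self):
        atoms = [
            make_atom(1, [0.0, 0, 0], name="C1", residue_seq=1, chain_id="1"),
            make_atom(2, [1.0, 0, 0], name="C2", residue_seq=1, chain_id="1"),
            make_atom(3, [9.0, 0, 0], name="C1", residue_seq=2, chain_id="1"),
        ]
        frags = PlacedFragment.from_atoms(atoms)
        assert sorted(f.probe.n_atoms for f in frags) == [1, 2]
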