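"""Ensemble-aggregated per-residue probe-interaction statistics.

This is the statistic that turns per-conformer hot spots into an
ensemble-level residue ranking: an interaction is counted whenever a
non-hydrogen probe atom of a consensus-site pose lies within the contact
radius (default 5 Å, inclusive) of a non-hydrogen protein atom.  Counts
are summed over all mapped conformers, expressed as a percentage of all
protein-probe contacts in the ensemble, and ranked.  Residues near the
reference ligand are classified orthosteric; the remaining top-ranked
residues are grouped into candidate (putative allosteric) sites by
single linkage on minimal heavy-atom distance in a reference structure.

Counting is at the atom-pair level: a probe atom within reach of three
atoms of one residue contributes three counts to that residue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .probe_mapping import Pose
from .structure_io import ResidueKey, Structure

__all__ = [
    "ProfilingConfig",
    "ResidueProfile",
    "SiteGroup",
    "count_contacts",
    "aggregate_profiles",
    "classify_orthosteric",
    "select_top_n",
    "group_sites",
]


class PlacedFragment:
    """A probe pose reconstructed from written coordinates alone.

    Mapped-structure PDB files carry probe poses as HETATM residues; on
    re-read the rigid-body parameters are gone but contact counting only
    needs coordinates.  Duck-types the ``Pose`` surface used here
    (``coords()`` and ``probe.n_atoms``).
    """

    class _Probe:
        def __init__(self, code: str, n_atoms: int):
            self.code = code
            self.name = code
            self.n_atoms = n_atoms

    def __init__(self, code: str, xyz: np.ndarray):
        self._xyz = np.asarray(xyz, dtype=float)
        self.probe = PlacedFragment._Probe(code, len(self._xyz))

    def coords(self) -> np.ndarray:
        return self._xyz

    @staticmethod
    def from_atoms(atoms) -> list["PlacedFragment"]:
        """Group HETATM records into one fragment per residue."""
        fragments: dict[tuple, list] = {}
        codes: dict[tuple, str] = {}
        for a in atoms:
            if not a.is_heavy:
                continue
            key = (a.chain_id, a.residue_seq, a.icode)
            fragments.setdefault(key, []).append(a.coords)
            codes[key] = a.residue_name
        return [
            PlacedFragment(codes[key], np.array(xyz))
            for key, xyz in fragments.items()
        ]


@dataclass
class ProfilingConfig:
    contact_radius: float = 5.0      # A, probe-protein heavy-atom contact
    top_n: int = 40                  # residues kept for site analysis
    orthosteric_radius: float = 5.0  # A, residue-to-ligand classification
    site_linkage_cutoff: float = 5.0  # A, min heavy-atom single linkage
    #: minimum Jaccard overlap of two residues' contacting-pose sets for
    #: them to join the same site (see :func:`group_sites`); 0 disables
    pose_overlap_min: float = 0.2

    def __post_init__(self) -> None:
        for name in ("contact_radius", "top_n", "orthosteric_radius", "site_linkage_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.pose_overlap_min <= 1.0):
            raise ValueError("pose_overlap_min must be in [0, 1]")


@dataclass
class ResidueProfile:
    """Contact statistics of one residue, aggregated over the ensemble."""

    residue_key: ResidueKey
    raw_count: int
    percentage: float = 0.0
    rank: int = 0
    orthosteric: bool = False


@dataclass
class SiteGroup:
    """A spatial group of non-orthosteric top residues plus their probes.

    ``annotation`` is a free-form environment tag (e.g. solvent- or
    lipid-facing) that callers may attach; the package does not compute
    exposure itself.
    """

    site_id: int
    residues: list[ResidueKey]
    summed_percentage: float
    member_probes: list[Pose] = field(default_factory=list)
    annotation: str = ""


def count_contacts(
    structure: Structure, poses: Sequence[Pose], config: ProfilingConfig
) -> dict[ResidueKey, int]:
    """Heavy-atom pair contacts per residue for one mapped conformer.

    For every pose, every (probe heavy atom, protein heavy atom) pair at
    distance <= ``contact_radius`` increments the protein atom's residue.
    The boundary is inclusive.  An empty pose list yields an all-zero map.
    """
    counts: dict[ResidueKey, int] = {key: 0 for key in structure.residue_index}
    heavy_idx = np.flatnonzero(structure.heavy_mask)
    if len(heavy_idx) == 0 or not poses:
        return counts
    tree = cKDTree(structure.coords[heavy_idx])
    atom_residue = [structure.atoms[i].residue_key for i in heavy_idx]
    for pose in poses:
        xyz = pose.coords()
        for a in range(pose.probe.n_atoms):
            for j in tree.query_ball_point(xyz[a], config.contact_radius):
                counts[atom_residue[j]] += 1
    return counts


def aggregate_profiles(
    per_structure_counts: Iterable[dict[ResidueKey, int]],
) -> list[ResidueProfile]:
    """Sum counts over conformers and rank residues by ensemble share.

    Percentages are of the grand total over all residues and conformers
    (summing to 100 when nonzero).  Ranking is by raw count descending,
    ties by residue key (chain, then lower residue number).
    """
    totals: dict[ResidueKey, int] = {}
    for counts in per_structure_counts:
        for key, c in counts.items():
            totals[key] = totals.get(key, 0) + c
    grand = sum(totals.values())
    if grand == 0:
        warnings.warn("no protein-probe contacts found; percentages are zero")
    profiles = [
        ResidueProfile(residue_key=key, raw_count=c) for key, c in totals.items()
    ]
    profiles.sort(key=lambda p: (-p.raw_count, p.residue_key))
    for rank, p in enumerate(profiles, start=1):
        p.rank = rank
        p.percentage = 100.0 * p.raw_count / grand if grand else 0.0
    return profiles


def classify_orthosteric(
    profiles: list[ResidueProfile],
    reference: Structure,
    ligand: Structure | None,
    config: ProfilingConfig,
) -> list[ResidueProfile]:
    """Flag residues with any heavy atom within ``orthosteric_radius`` of
    any ligand heavy atom (measured in the reference structure).

    A missing ligand leaves every residue non-orthosteric with a warning.
    """
    if ligand is None or not ligand.heavy_mask.any():
        warnings.warn("no reference ligand; all residues classified non-orthosteric")
        for p in profiles:
            p.orthosteric = False
        return profiles
    lig_xyz = ligand.coords[ligand.heavy_mask]
    tree = cKDTree(lig_xyz)
    for p in profiles:
        lo, hi = reference.residue_index[p.residue_key]
        res_xyz = np.array(
            [a.coords for a in reference.atoms[lo:hi] if a.is_heavy]
        )
        if len(res_xyz) == 0:
            p.orthosteric = False
            continue
        d, _ = tree.query(res_xyz, k=1)
        p.orthosteric = bool(d.min() <= config.orthosteric_radius)
    return profiles


def select_top_n(
    profiles: list[ResidueProfile], config: ProfilingConfig
) -> list[ResidueProfile]:
    """First ``top_n`` ranked profiles with nonzero contact counts."""
    ranked = sorted(profiles, key=lambda p: p.rank)
    nonzero = [p for p in ranked if p.raw_count > 0]
    return nonzero[: config.top_n]


def pose_contact_sets(
    structure: Structure, poses: Sequence[Pose], config: ProfilingConfig
) -> list[set[ResidueKey]]:
    """Residues each pose contacts (heavy-atom pairs within contact_radius),
    evaluated in the pose's own conformer frame."""
    heavy_idx = np.flatnonzero(structure.heavy_mask)
    tree = cKDTree(structure.coords[heavy_idx])
    atom_residue = [structure.atoms[i].residue_key for i in heavy_idx]
    out = []
    for pose in poses:
        keys: set[ResidueKey] = set()
        xyz = pose.coords()
        for a in range(pose.probe.n_atoms):
            for j in tree.query_ball_point(xyz[a], config.contact_radius):
                keys.add(atom_residue[j])
        out.append(keys)
    return out


def group_sites(
    top_profiles: list[ResidueProfile],
    reference: Structure,
    poses: Sequence[Pose],
    config: ProfilingConfig,
    pose_contacts: Sequence[set[ResidueKey]] | None = None,
) -> list[SiteGroup]:
    """Grouping of non-orthosteric top residues into candidate sites.

    Two residues join the same site (single linkage, chained) when their
    minimal heavy-atom distance in the reference structure is
    <= ``site_linkage_cutoff`` *and* — when pose information is available
    and ``pose_overlap_min`` > 0 — the sets of poses contacting them
    overlap with Jaccard >= ``pose_overlap_min``.  The co-binding term
    expresses that a site is a set of residues together with the probes
    they bind: two spatially adjacent residues that are contacted by
    essentially disjoint probe populations belong to different sites.
    Without poses the linkage is purely spatial.

    Sites are numbered by descending summed percentage; every pose that
    contacts any residue of a site is attached to it.  When poses come
    from several conformers, pass ``pose_contacts`` (one contacted
    residue-key set per pose, from :func:`pose_contact_sets` evaluated in
    each pose's own conformer); otherwise contacts are measured against
    the reference coordinates.
    """
    non_ortho = [p for p in top_profiles if not p.orthosteric]
    if not non_ortho:
        return []
    if poses and pose_contacts is None:
        pose_contacts = pose_contact_sets(reference, poses, config)
    res_xyz = []
    for p in non_ortho:
        lo, hi = reference.residue_index[p.residue_key]
        res_xyz.append(
            np.array([a.coords for a in reference.atoms[lo:hi] if a.is_heavy])
        )
    n = len(non_ortho)
    pose_sets: list[set[int]] = [set() for _ in range(n)]
    if poses and config.pose_overlap_min > 0:
        key_to_idx = {p.residue_key: i for i, p in enumerate(non_ortho)}
        for pi, contacted in enumerate(pose_contacts):
            for key in contacted:
                if key in key_to_idx:
                    pose_sets[key_to_idx[key]].add(pi)
    use_overlap = poses and config.pose_overlap_min > 0
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n):
        adj[i, i] = True
        for j in range(i + 1, n):
            d = np.linalg.norm(
                res_xyz[i][:, None, :] - res_xyz[j][None, :, :], axis=-1
            ).min()
            if d > config.site_linkage_cutoff:
                continue
            if use_overlap:
                a, b = pose_sets[i], pose_sets[j]
                if a and b:
                    jac = len(a & b) / len(a | b)
                    if jac < config.pose_overlap_min:
                        continue
            adj[i, j] = adj[j, i] = True
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    groups = []
    for comp in range(n_comp):
        idx = np.flatnonzero(labels == comp)
        members = [non_ortho[i] for i in idx]
        members.sort(key=lambda p: p.residue_key)
        groups.append(
            SiteGroup(
                site_id=0,
                residues=[p.residue_key for p in members],
                summed_percentage=float(sum(p.percentage for p in members)),
            )
        )
    groups.sort(key=lambda g: (-g.summed_percentage, g.residues[0]))
    for sid, g in enumerate(groups, start=1):
        g.site_id = sid

    # attach poses by contact with any site residue
    if poses:
        if pose_contacts is None:
            pose_contacts = pose_contact_sets(reference, poses, config)
        keysets = [set(g.residues) for g in groups]
        for pose, contacted in zip(poses, pose_contacts):
            for g_i, keys in enumerate(keysets):
                if keys & contacted:
                    groups[g_i].member_probes.append(pose)
    return groups
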