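"""Single-structure multi-probe hot-spot mapping.

The mapping protocol docks a library of 16 rigid organic probe fragments
over the entire receptor surface, then aggregates where different probe
types congregate:

1. per-probe exhaustive rigid-body search (quasi-uniform rotations x all
   translations of a regular grid) scored on precomputed energy grids;
2. retention of the ``poses_retained`` (default 2000) lowest-energy poses;
3. local rigid-body energy minimization of the retained poses against the
   direct pair-sum energy;
4. greedy energy-ordered clustering of minimized poses, keeping the
   ``clusters_per_probe`` (default 6) clusters of lowest mean energy;
5. single-linkage aggregation of the retained clusters of *all* probes
   into consensus sites (CSs), ranked by the number of probe clusters
   they incorporate; the ``top_cs`` (default 10) largest are reported.

The energy model is a transparent stand-in for empirical hot-spot scoring
functions: Lennard-Jones 12-6 on a small internal atom-class table with
Lorentz-Berthelot combining, plus Coulomb electrostatics with a
distance-dependent dielectric eps(r) = 4r, truncated at 8 A, with a
+100 kJ/mol per-pair clash cap.  No solvation term is included.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.stats import qmc

from . import _kernels
from .probes import ATOM_CLASSES, ProbeType, default_probe_library
from .structure_io import Structure

__all__ = [
    "MappingConfig",
    "EnergyGrid",
    "Pose",
    "PoseCluster",
    "ConsensusSite",
    "MappingResult",
    "build_energy_grids",
    "pose_energy",
    "sample_poses",
    "minimize_pose",
    "minimize_poses",
    "cluster_poses",
    "build_consensus_sites",
    "map_structure",
]

#: Coulomb constant in kJ/mol * A / e^2
COULOMB_K = 1389.35458

#: LJ channel order of the energy grids (all probe heavy-atom classes)
PROBE_CHANNEL_CLASSES = ("C3", "C2", "C1", "CAR", "CO", "O", "OH", "OE", "N", "NC")


def lorentz_berthelot(class_a: str, class_b: str) -> tuple[float, float]:
    sa, ea = ATOM_CLASSES[class_a]
    sb, eb = ATOM_CLASSES[class_b]
    return 0.5 * (sa + sb), math.sqrt(ea * eb)


@dataclass
class MappingConfig:
    """Knobs of the mapping protocol.

    ``poses_retained``, ``clusters_per_probe`` and ``top_cs`` are protocol
    constants of the method; the geometric cutoffs and the grid/rotation
    resolution are implementation choices exposed for reproducibility.
    ``sample_shell``, when set to ``(lo, hi)``, restricts candidate
    translations to grid points whose distance to the nearest receptor
    heavy atom lies in that band — a performance device for
    receptor-sized systems where well over ``poses_retained`` strongly
    negative candidates exist inside the band; ``None`` (default) scores
    every grid translation.
    """

    grid_spacing: float = 0.8          # A, translation lattice
    grid_oversample: int = 5           # interpolation sub-grid refinement
    rotation_count: int = 500
    poses_retained: int = 2000
    clusters_per_probe: int = 6
    pose_cluster_cutoff: float = 3.0   # A, probe-atom RMSD in receptor frame
    cs_linkage_cutoff: float = 4.0     # A, center-to-center single linkage
    top_cs: int = 10
    dielectric: str = "4r"             # distance-dependent eps(r) = 4r
    clash_cap: float = 100.0           # kJ/mol per pair
    nonbonded_cutoff: float = 8.0      # A
    grid_margin: float = 8.0           # A beyond receptor bounding box
    sample_shell: tuple[float, float] | None = None
    minimize_max_iter: int = 80
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "grid_spacing",
            "poses_retained",
            "clusters_per_probe",
            "pose_cluster_cutoff",
            "cs_linkage_cutoff",
            "top_cs",
            "clash_cap",
            "nonbonded_cutoff",
            "grid_margin",
            "minimize_max_iter",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.rotation_count < 1:
            raise ValueError("rotation_count must be >= 1")
        if self.grid_oversample < 1:
            raise ValueError("grid_oversample must be >= 1")
        if self.grid_margin < self.nonbonded_cutoff:
            # outside-box contributions are treated as exactly zero, which
            # is only correct when the box covers the full cutoff reach
            raise ValueError("grid_margin must be >= nonbonded_cutoff")
        if self.dielectric != "4r":
            raise ValueError("only the distance-dependent dielectric '4r' is supported")
        if self.sample_shell is not None:
            lo, hi = self.sample_shell
            if not (0.0 <= lo < hi):
                raise ValueError("sample_shell must be (lo, hi) with 0 <= lo < hi")


@dataclass
class EnergyGrid:
    """Per-class LJ potential grids plus an electrostatic potential grid.

    ``lj_channels[c]`` holds, at every sub-grid point, the summed capped
    LJ energy a probe atom of class ``PROBE_CHANNEL_CLASSES[c]`` would
    feel; ``elec`` holds the Coulomb potential per unit probe charge
    (same truncation).  Candidate translations live on the coarser
    ``spacing`` lattice (``dims``); interpolation uses the
    ``oversample``-times finer sub-grid (``sub_dims``), which bounds the
    trilinear error near the steep LJ wall.  ``min_dist`` caches each
    translation-lattice point's distance to the nearest receptor heavy
    atom.
    """

    origin: np.ndarray
    spacing: float
    oversample: int
    dims: tuple[int, int, int]
    sub_dims: tuple[int, int, int]
    lj_channels: np.ndarray
    elec: np.ndarray
    receptor_xyz: np.ndarray
    min_dist: np.ndarray

    @property
    def sub_spacing(self) -> float:
        return self.spacing / self.oversample

    def grid_points(self) -> np.ndarray:
        """Translation-lattice points, flat (M, 3)."""
        nx, ny, nz = self.dims
        ii = np.stack(
            np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"),
            axis=-1,
        ).reshape(-1, 3)
        return self.origin + ii * self.spacing

    def interpolate(self, channel: int | None, points: np.ndarray) -> np.ndarray:
        """Trilinear sub-grid interpolation (LJ channel, or elec if None)."""
        field = self.elec if channel is None else self.lj_channels[channel]
        pts = (np.atleast_2d(points) - self.origin) / self.sub_spacing
        out = np.empty(len(pts))
        for i, (x, y, z) in enumerate(pts):
            out[i] = _kernels._trilinear(field, float(x), float(y), float(z))
        return out


@dataclass
class Pose:
    """A rigid placement of a probe: rotation (unit quaternion, w-first),
    translation of the body centroid, and its interaction energy."""

    probe: ProbeType
    rotation: np.ndarray
    translation: np.ndarray
    energy: float
    converged: bool = True

    def __post_init__(self) -> None:
        q = np.asarray(self.rotation, dtype=float)
        if abs(np.linalg.norm(q) - 1.0) > 1e-9:
            raise ValueError("pose quaternion must be unit length")
        if not np.isfinite(self.energy):
            raise ValueError("pose energy must be finite")
        object.__setattr__(self, "rotation", q)
        object.__setattr__(
            self, "translation", np.asarray(self.translation, dtype=float)
        )

    def matrix(self) -> np.ndarray:
        w, x, y, z = self.rotation
        return Rotation.from_quat([x, y, z, w]).as_matrix()

    def coords(self) -> np.ndarray:
        """(A, 3) probe heavy-atom coordinates in the receptor frame."""
        return self.probe.coords @ self.matrix().T + self.translation

    def centroid(self) -> np.ndarray:
        return self.translation

    def placed_atoms(self):
        """Yield (name, element, xyz, charge) per atom, for PDB output."""
        xyz = self.coords()
        for i in range(self.probe.n_atoms):
            yield (
                self.probe.atom_names[i],
                self.probe.elements[i],
                xyz[i],
                self.probe.charges[i],
            )


@dataclass
class PoseCluster:
    """Poses of one probe type within the pose-cluster RMSD cutoff of the
    lowest-energy member (the cluster center)."""

    probe: ProbeType
    members: list[Pose]
    center: Pose
    mean_energy: float

    @property
    def size(self) -> int:
        return len(self.members)

    def centroid(self) -> np.ndarray:
        return self.center.centroid()


@dataclass
class ConsensusSite:
    """A cross-probe aggregate of pose clusters: a candidate hot spot."""

    rank: int
    member_clusters: list[PoseCluster]
    center_of_mass: np.ndarray

    @property
    def size(self) -> int:
        return len(self.member_clusters)

    @property
    def mean_energy(self) -> float:
        return float(np.mean([c.mean_energy for c in self.member_clusters]))

    def probe_names(self) -> list[str]:
        return sorted({c.probe.name for c in self.member_clusters})

    def poses(self) -> list[Pose]:
        return [p for c in self.member_clusters for p in c.members]


@dataclass
class MappingResult:
    """Outcome of mapping one structure."""

    structure_id: int
    consensus_sites: list[ConsensusSite]
    probe_clusters: dict[str, list[PoseCluster]]

    def cs_poses(self) -> list[Pose]:
        """All poses belonging to the retained consensus sites."""
        return [p for site in self.consensus_sites for p in site.poses()]


# ---------------------------------------------------------------------------
# energy grids and direct energies


def _receptor_tables(
    receptor: Structure, atom_classes: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Heavy-atom coordinates/charges and per-(class, atom) LJ tables."""
    heavy = receptor.heavy_mask
    xyz = receptor.coords[heavy]
    charges = receptor.charges[heavy]
    rec_classes = [a.atom_class for a, h in zip(receptor.atoms, heavy) if h]
    C = len(atom_classes)
    R = len(rec_classes)
    sigma = np.empty((C, R))
    eps = np.empty((C, R))
    for c, cls in enumerate(atom_classes):
        for i, rcls in enumerate(rec_classes):
            sigma[c, i], eps[c, i] = lorentz_berthelot(cls, rcls)
    return xyz, charges, sigma, eps


def build_energy_grids(receptor: Structure, config: MappingConfig) -> EnergyGrid:
    """Precompute LJ channel grids and the electrostatic grid.

    The box encloses all receptor heavy atoms plus ``grid_margin``, which
    defaults to the nonbonded cutoff plus the largest probe radius so that
    no in-range interaction is lost at the box boundary.
    """
    heavy = receptor.heavy_mask
    if not heavy.any():
        raise ValueError("receptor has no heavy atoms")
    xyz, charges, sigma, eps = _receptor_tables(receptor, PROBE_CHANNEL_CLASSES)
    lo = xyz.min(axis=0) - config.grid_margin
    hi = xyz.max(axis=0) + config.grid_margin
    dims = tuple(int(np.ceil((hi[d] - lo[d]) / config.grid_spacing)) + 1 for d in range(3))
    ov = int(config.grid_oversample)
    sub_dims = tuple((d - 1) * ov + 1 for d in dims)
    n_bytes = (len(PROBE_CHANNEL_CLASSES) + 1) * float(np.prod(sub_dims)) * 4
    if n_bytes > 4e9:
        raise MemoryError(
            f"energy grid of sub-dims {sub_dims} would need {n_bytes / 1e9:.1f} GB; "
            "increase grid_spacing or reduce grid_margin/grid_oversample"
        )
    lj = np.zeros((len(PROBE_CHANNEL_CLASSES),) + sub_dims, dtype=np.float32)
    elec = np.zeros(sub_dims, dtype=np.float32)
    _kernels.accumulate_grid(
        lj,
        elec,
        lo.astype(float),
        float(config.grid_spacing) / ov,
        xyz,
        charges,
        sigma,
        eps,
        float(config.nonbonded_cutoff),
        float(config.clash_cap),
        COULOMB_K / 4.0,
    )
    grid = EnergyGrid(
        origin=lo,
        spacing=float(config.grid_spacing),
        oversample=ov,
        dims=dims,
        sub_dims=sub_dims,
        lj_channels=lj,
        elec=elec,
        receptor_xyz=xyz,
        min_dist=np.empty(0),
    )
    tree = cKDTree(xyz)
    dist, _ = tree.query(grid.grid_points(), k=1)
    grid.min_dist = dist.reshape(dims)
    return grid


def pose_energy(receptor: Structure, pose: Pose, config: MappingConfig) -> float:
    """Direct (non-grid) pair-sum energy of a pose: the oracle the grid
    scoring approximates and the objective the minimizer descends."""
    heavy = receptor.heavy_mask
    rxyz = receptor.coords[heavy]
    rq = receptor.charges[heavy]
    rcls = [a.atom_class for a, h in zip(receptor.atoms, heavy) if h]
    pxyz = pose.coords()
    total = 0.0
    cutoff2 = config.nonbonded_cutoff**2
    for a in range(pose.probe.n_atoms):
        d = rxyz - pxyz[a]
        r2 = np.einsum("ij,ij->i", d, d)
        mask = r2 <= cutoff2
        if not mask.any():
            continue
        r2m = np.maximum(r2[mask], 1e-12)
        cls_a = pose.probe.atom_classes[a]
        sig = np.array([lorentz_berthelot(cls_a, rcls[i])[0] for i in np.flatnonzero(mask)])
        epsv = np.array([lorentz_berthelot(cls_a, rcls[i])[1] for i in np.flatnonzero(mask)])
        s6 = (sig**2 / r2m) ** 3
        lj = 4.0 * epsv * (s6**2 - s6)
        total += float(np.minimum(lj, config.clash_cap).sum())
        qq = pose.probe.charges[a] * rq[mask]
        r2c = np.maximum(r2m, _kernels.R_CLAMP**2)
        total += float((COULOMB_K / 4.0 * qq / r2c).sum())
    return total


# ---------------------------------------------------------------------------
# rotation set and exhaustive sampling


def rotation_set(count: int, seed: int) -> np.ndarray:
    """(K, 4) quasi-uniform unit quaternions (w-first), deterministic for
    a fixed seed (scrambled Halton sequence + Shoemake mapping)."""
    halton = qmc.Halton(d=3, scramble=True, seed=seed)
    u = halton.random(count)
    q = np.empty((count, 4))
    q[:, 0] = np.sqrt(u[:, 0]) * np.cos(2 * np.pi * u[:, 2])
    q[:, 1] = np.sqrt(1 - u[:, 0]) * np.sin(2 * np.pi * u[:, 1])
    q[:, 2] = np.sqrt(1 - u[:, 0]) * np.cos(2 * np.pi * u[:, 1])
    q[:, 3] = np.sqrt(u[:, 0]) * np.sin(2 * np.pi * u[:, 2])
    return q


def _quat_matrices(quats: np.ndarray) -> np.ndarray:
    return Rotation.from_quat(quats[:, [1, 2, 3, 0]]).as_matrix()


def sample_poses(
    grids: EnergyGrid, probe: ProbeType, config: MappingConfig
) -> list[Pose]:
    """Exhaustive rotation x translation search on the energy grids.

    Scores every rotation of the probe at every candidate grid point and
    returns the ``poses_retained`` lowest-energy poses, sorted ascending,
    ties broken by (rotation index, grid point index).  Grid points whose
    surroundings cannot interact with the receptor (beyond cutoff + probe
    radius) contribute exact-zero candidates and are materialized only if
    needed to fill the retained set.
    """
    quats = rotation_set(config.rotation_count, config.seed)
    mats = _quat_matrices(quats)
    rot_bodies = np.einsum("kij,aj->kai", mats, probe.coords) / grids.sub_spacing

    mind = grids.min_dist.reshape(-1)
    reach = config.nonbonded_cutoff + probe.radius
    if config.sample_shell is not None:
        lo, hi = config.sample_shell
        cand_mask = (mind >= lo) & (mind <= hi)
        zero_mask = mind > reach  # exact-zero poses remain mergeable
    else:
        cand_mask = mind <= reach
        zero_mask = ~cand_mask
    cand_flat = np.flatnonzero(cand_mask)
    # candidate centroid positions in sub-grid index units
    cand_idx = (
        np.stack(np.unravel_index(cand_flat, grids.dims), axis=1).astype(np.float64)
        * grids.oversample
    )

    # per-atom global lower bounds for the branch-and-bound pruning
    cls_idx = np.array(
        [PROBE_CHANNEL_CLASSES.index(c) for c in probe.atom_classes], dtype=np.int64
    )
    lj_min = np.array([float(grids.lj_channels[c].min()) for c in range(len(PROBE_CHANNEL_CLASSES))])
    elec_min = float(grids.elec.min())
    elec_max = float(grids.elec.max())
    atom_lb = np.minimum(
        0.0,
        lj_min[cls_idx]
        + np.where(probe.charges > 0, probe.charges * elec_min, probe.charges * elec_max),
    )
    suffix_lb = np.zeros(probe.n_atoms + 1)
    suffix_lb[:-1] = np.cumsum(atom_lb[::-1])[::-1]

    K = config.rotation_count
    pool_e: list[np.ndarray] = []
    pool_rot: list[np.ndarray] = []
    pool_flat: list[np.ndarray] = []
    block = max(1, int(2_000_000 // max(1, len(cand_flat))))
    M = len(cand_flat)
    threshold = np.inf
    n_pool = 0
    for k0 in range(0, K, block):
        k1 = min(K, k0 + block)
        out = np.empty((k1 - k0, M))
        _kernels.score_rotations(
            grids.lj_channels,
            grids.elec,
            rot_bodies[k0:k1],
            cls_idx,
            probe.charges,
            cand_idx,
            suffix_lb,
            threshold,
            out,
        )
        e = out.reshape(-1)
        rots = np.repeat(np.arange(k0, k1), M)
        flats = np.tile(cand_flat, k1 - k0)
        keep = e < _kernels.EXCLUDED
        e, rots, flats = e[keep], rots[keep], flats[keep]
        if len(e) > config.poses_retained:
            part = np.partition(e, config.poses_retained - 1)
            thresh = part[config.poses_retained - 1]
            keep = e <= thresh
            e, rots, flats = e[keep], rots[keep], flats[keep]
        pool_e.append(e)
        pool_rot.append(rots)
        pool_flat.append(flats)
        n_pool += len(e)
        if n_pool >= config.poses_retained:
            pooled = np.concatenate(pool_e)
            threshold = float(
                np.partition(pooled, config.poses_retained - 1)[
                    config.poses_retained - 1
                ]
            )

    e = np.concatenate(pool_e) if pool_e else np.empty(0)
    rots = np.concatenate(pool_rot) if pool_rot else np.empty(0, dtype=int)
    flats = np.concatenate(pool_flat) if pool_flat else np.empty(0, dtype=int)

    # merge exact-zero candidates if the retained set would otherwise be
    # short or include positive-energy poses
    n_zero_points = int(zero_mask.sum())
    need_zeros = n_zero_points > 0 and (
        len(e) < config.poses_retained
        or np.sort(e)[: config.poses_retained][-1] > 0.0
    )
    if need_zeros:
        zero_flats = np.flatnonzero(zero_mask)
        needed = config.poses_retained
        zr_list, zf_list = [], []
        r = 0
        while needed > 0 and r < K:
            take = min(needed, n_zero_points)
            zr_list.append(np.full(take, r))
            zf_list.append(zero_flats[:take])
            needed -= take
            r += 1
        zf = np.concatenate(zf_list)
        e = np.concatenate([e, np.zeros(len(zf))])
        rots = np.concatenate([rots, np.concatenate(zr_list)])
        flats = np.concatenate([flats, zf])

    order = np.lexsort((flats, rots, e))[: config.poses_retained]
    poses = []
    for j in order:
        gi = np.unravel_index(int(flats[j]), grids.dims)
        t = grids.origin + np.array(gi) * grids.spacing
        poses.append(
            Pose(
                probe=probe,
                rotation=quats[int(rots[j])] / np.linalg.norm(quats[int(rots[j])]),
                translation=t,
                energy=float(e[j]),
            )
        )
    return poses


# ---------------------------------------------------------------------------
# minimization


def _probe_pair_tables(probe: ProbeType, receptor: Structure):
    heavy = receptor.heavy_mask
    rxyz = receptor.coords[heavy]
    rq = receptor.charges[heavy]
    rcls = [a.atom_class for a, h in zip(receptor.atoms, heavy) if h]
    A, R = probe.n_atoms, len(rcls)
    sigma = np.empty((A, R))
    eps = np.empty((A, R))
    for a, cls_a in enumerate(probe.atom_classes):
        for i, rc in enumerate(rcls):
            sigma[a, i], eps[a, i] = lorentz_berthelot(cls_a, rc)
    qpref = COULOMB_K / 4.0 * np.outer(probe.charges, rq)
    return rxyz, sigma, eps, qpref


def minimize_poses(
    receptor: Structure, poses: Sequence[Pose], config: MappingConfig
) -> list[Pose]:
    """Batched local rigid-body (6-DOF) minimization of the direct energy.

    Gradient descent with per-pose backtracking: the returned energy never
    exceeds the direct energy of the input pose.  Non-convergence within
    ``minimize_max_iter`` returns the best pose so far, flagged.
    """
    if not poses:
        return []
    probe = poses[0].probe
    if any(p.probe is not probe and p.probe.name != probe.name for p in poses):
        raise ValueError("minimize_poses expects poses of a single probe type")
    rxyz, sigma, eps, qpref = _probe_pair_tables(probe, receptor)
    quats = np.array([p.rotation for p in poses], dtype=float)
    trans = np.array([p.translation for p in poses], dtype=float)
    energies = np.empty(len(poses))
    converged = np.zeros(len(poses), dtype=np.uint8)
    _kernels.minimize_batch(
        probe.coords,
        quats,
        trans,
        rxyz,
        sigma,
        eps,
        qpref,
        float(config.nonbonded_cutoff),
        float(config.clash_cap),
        int(config.minimize_max_iter),
        energies,
        converged,
    )
    out = []
    for j, p in enumerate(poses):
        q = quats[j] / np.linalg.norm(quats[j])
        out.append(
            Pose(
                probe=probe,
                rotation=q,
                translation=trans[j],
                energy=float(energies[j]),
                converged=bool(converged[j]),
            )
        )
    return out


def minimize_pose(receptor: Structure, pose: Pose, config: MappingConfig) -> Pose:
    """Single-pose wrapper around :func:`minimize_poses`."""
    return minimize_poses(receptor, [pose], config)[0]


# ---------------------------------------------------------------------------
# clustering


def cluster_poses(poses: Sequence[Pose], config: MappingConfig) -> list[PoseCluster]:
    """Greedy energy-ordered clustering of same-probe poses.

    The lowest-energy unassigned pose seeds a cluster and all unassigned
    poses within ``pose_cluster_cutoff`` probe-atom RMSD (receptor frame,
    no re-superposition) join it.  The ``clusters_per_probe`` clusters of
    lowest mean energy are retained.
    """
    if not poses:
        return []
    order = sorted(range(len(poses)), key=lambda i: (poses[i].energy, i))
    coords = np.array([poses[i].coords() for i in order])
    n, A, _ = coords.shape
    unassigned = np.ones(n, dtype=bool)
    clusters: list[PoseCluster] = []
    while unassigned.any():
        seed = int(np.flatnonzero(unassigned)[0])
        diff = coords[unassigned] - coords[seed]
        rmsd = np.sqrt(np.einsum("nad,nad->n", diff, diff) / A)
        members_rel = np.flatnonzero(unassigned)[rmsd <= config.pose_cluster_cutoff]
        member_poses = [poses[order[i]] for i in members_rel]
        clusters.append(
            PoseCluster(
                probe=poses[0].probe,
                members=member_poses,
                center=poses[order[seed]],
                mean_energy=float(np.mean([p.energy for p in member_poses])),
            )
        )
        unassigned[members_rel] = False
    clusters.sort(key=lambda c: (c.mean_energy, c.center.energy))
    return clusters[: config.clusters_per_probe]


def build_consensus_sites(
    clusters: Iterable[PoseCluster], config: MappingConfig
) -> list[ConsensusSite]:
    """Single-linkage aggregation of probe clusters into ranked CSs.

    Cluster-center distance is the distance between center-pose centroids;
    components at ``cs_linkage_cutoff`` form the CSs.  Ranking: size
    descending, ties by lower aggregate mean energy, then by the
    lexicographically first member probe name.  ``top_cs`` sites are kept.
    """
    clusters = list(clusters)
    if not clusters:
        return []
    centroids = np.array([c.centroid() for c in clusters])
    d = np.linalg.norm(centroids[:, None, :] - centroids[None, :, :], axis=-1)
    adj = csr_matrix(d <= config.cs_linkage_cutoff)
    n_comp, labels = connected_components(adj, directed=False)
    sites = []
    for comp in range(n_comp):
        members = [clusters[i] for i in np.flatnonzero(labels == comp)]
        members.sort(key=lambda c: (c.mean_energy, c.probe.name))
        com = np.mean([c.centroid() for c in members], axis=0)
        sites.append(ConsensusSite(rank=0, member_clusters=members, center_of_mass=com))
    sites.sort(
        key=lambda s: (
            -s.size,
            s.mean_energy,
            min(c.probe.name for c in s.member_clusters),
        )
    )
    sites = sites[: config.top_cs]
    for rank, site in enumerate(sites, start=1):
        site.rank = rank
    return sites


# ---------------------------------------------------------------------------
# end-to-end


def map_structure(
    receptor: Structure,
    config: MappingConfig,
    probes: Sequence[ProbeType] | None = None,
) -> MappingResult:
    """Run the full mapping protocol on one receptor conformation.

    Deterministic for a fixed config (the rotation set derives from
    ``config.seed``).
    """
    if probes is None:
        probes = default_probe_library()
    grids = build_energy_grids(receptor, config)
    probe_clusters: dict[str, list[PoseCluster]] = {}
    for probe in probes:
        retained = sample_poses(grids, probe, config)
        minimized = minimize_poses(receptor, retained, config)
        probe_clusters[probe.name] = cluster_poses(minimized, config)
    all_clusters = [c for cl in probe_clusters.values() for c in cl]
    sites = build_consensus_sites(all_clusters, config)
    return MappingResult(
        structure_id=receptor.model_id,
        consensus_sites=sites,
        probe_clusters=probe_clusters,
    )
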