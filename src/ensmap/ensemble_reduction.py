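"""Conformer-ensemble reduction: superposition, RMSD, neighbor clustering.

A long trajectory is reduced to a handful of representative structures in
three steps: least-squares (Kabsch) superposition of every conformer onto
a common selection, an all-pairs RMSD matrix over that same selection,
and GROMOS-style neighbor clustering (Daura et al.): the structure with
the most neighbors within the cutoff seeds a cluster and is removed with
its neighbors, iterating until no structures remain.  The cluster centers
of the top ``k`` clusters (default 15, cutoff 1.5 Å) become the
representative ensemble, and the report records which fraction of the
trajectory they account for.

Tie-breaking is everywhere by lowest model id, which makes the reduction
deterministic under relabeling; the cluster "center" is the max-neighbor
(centroid) structure of its cluster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .structure_io import ConformerEnsemble, Structure

__all__ = [
    "RmsdMatrix",
    "StructureCluster",
    "ReductionReport",
    "DegenerateSelectionError",
    "kabsch_superpose",
    "superpose_structure",
    "pairwise_rmsd_matrix",
    "gromos_cluster",
    "select_representatives",
]


class DegenerateSelectionError(ValueError):
    """Superposition selection is collinear or coincident."""


@dataclass
class RmsdMatrix:
    """Symmetric all-pairs RMSD matrix (Å, zero diagonal)."""

    n: int
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.n, self.n):
            raise ValueError("matrix shape mismatch")
        if not np.allclose(v, v.T, atol=1e-10) or np.abs(np.diag(v)).max() > 1e-10:
            raise ValueError("RMSD matrix must be symmetric with zero diagonal")
        if v.min() < 0:
            raise ValueError("RMSD entries must be non-negative")
        self.values = v


@dataclass
class StructureCluster:
    center_model: int
    member_models: list[int]

    @property
    def size(self) -> int:
        return len(self.member_models)


@dataclass
class ReductionReport:
    clusters: list[StructureCluster]
    cutoff: float
    k: int
    occupancy_of_top_k: float  # percent of models covered by the k retained


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    selection: list[int] | np.ndarray,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    The proper rotation ``R`` and translation ``t`` minimizing the RMSD of
    ``mobile[selection]`` against ``reference[selection]`` are returned
    together with that minimal RMSD; apply ``x @ R.T + t`` to transform
    *all* atoms of the mobile structure.

    Raises
    ------
    DegenerateSelectionError
        For fewer than 3 selected atoms or a collinear/coincident
        selection (the rotation is then not uniquely determined).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    sel = np.asarray(selection, dtype=int)
    if len(sel) < 3:
        raise DegenerateSelectionError("need at least 3 atoms for superposition")
    a = reference[sel]
    b = mobile[sel]
    if len(a) != len(b):
        raise ValueError("selection lengths differ")
    ca = a - a.mean(axis=0)
    cb = b - b.mean(axis=0)
    # rank < 2 => collinear or coincident points
    if np.linalg.matrix_rank(cb, tol=1e-8) < 2 or np.linalg.matrix_rank(ca, tol=1e-8) < 2:
        raise DegenerateSelectionError("selection is collinear or coincident")
    rot, rssd = Rotation.align_vectors(ca, cb)
    R = rot.as_matrix()
    t = a.mean(axis=0) - R @ b.mean(axis=0)
    rmsd = float(rssd / np.sqrt(len(sel)))
    return R, t, rmsd


def superpose_structure(
    mobile: Structure, reference: Structure, selection: list[int]
) -> tuple[Structure, float]:
    """Superpose a structure onto a reference; returns (moved, rmsd)."""
    R, t, rmsd = kabsch_superpose(mobile.coords, reference.coords, selection)
    return mobile.with_coords(mobile.coords @ R.T + t), rmsd


def pairwise_rmsd_matrix(ensemble: ConformerEnsemble) -> RmsdMatrix:
    """All-pairs superposed RMSD over the ensemble's alignment selection."""
    sel = np.asarray(ensemble.alignment_selection, dtype=int)
    if len(sel) < 3:
        raise DegenerateSelectionError("alignment selection too small")
    n = len(ensemble.models)
    coords = [m.coords[sel] for m in ensemble.models]
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, _, rmsd = kabsch_superpose(coords[j], coords[i], np.arange(len(sel)))
            values[i, j] = values[j, i] = rmsd
    return RmsdMatrix(n=n, values=values)


def gromos_cluster(matrix: RmsdMatrix, cutoff: float) -> list[StructureCluster]:
    """Daura neighbor clustering of an RMSD matrix.

    Repeatedly the structure with the most remaining neighbors within
    ``cutoff`` (inclusive; ties by lowest model id) becomes a cluster
    center and is removed together with its neighbors.  Clusters are
    returned ranked by size descending, ties by lower center id.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    n = matrix.n
    neighbor = matrix.values <= cutoff
    np.fill_diagonal(neighbor, False)
    remaining = np.ones(n, dtype=bool)
    clusters = []
    while remaining.any():
        counts = (neighbor & remaining[None, :] & remaining[:, None]).sum(axis=1)
        counts[~remaining] = -1
        center = int(np.argmax(counts))  # argmax returns lowest index on ties
        members = np.flatnonzero(neighbor[center] & remaining).tolist()
        members = sorted(set(members) | {center})
        clusters.append(StructureCluster(center_model=center, member_models=members))
        remaining[members] = False
    clusters.sort(key=lambda c: (-c.size, c.center_model))
    return clusters


def select_representatives(
    clusters: list[StructureCluster],
    ensemble: ConformerEnsemble,
    k: int = 15,
    cutoff: float = float("nan"),
) -> tuple[ConformerEnsemble, ReductionReport]:
    """Keep the top ``k`` clusters' center structures as representatives.

    Returns the representative ensemble (in cluster rank order, sharing
    the original alignment selection) and a report with the percentage of
    conformers the retained clusters cover.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    retained = clusters[: min(k, len(clusters))]
    covered = sum(c.size for c in retained)
    occupancy = 100.0 * covered / len(ensemble.models)
    reps = [ensemble.models[c.center_model] for c in retained]
    rep_ensemble = ConformerEnsemble(
        models=reps, alignment_selection=list(ensemble.alignment_selection)
    )
    report = ReductionReport(
        clusters=clusters,
        cutoff=cutoff,
        k=k,
        occupancy_of_top_k=occupancy,
    )
    return rep_ensemble, report
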