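"""Synthetic pseudo-receptor ensembles with planted, labelled pockets.

Real inputs to ensemble hot-spot mapping are membrane-receptor MD
trajectories, which are far outside desk scale.  This module generates a
compact stand-in that reproduces the two features the downstream stages
must detect: a constitutive "orthosteric" pocket holding a reference
ligand, and a cryptic "allosteric" pocket between two adjacent helices
that exists only in a subset of conformers.

Architecture
------------
A bundle of ``n_helices`` pseudo-helices (default 7) on a ring, each
residue contributing a backbone bead (``CA``) and one sidechain bead.
Sidechain beads either fan over the outer surface (phase-compressed
outward cone) or, for spiral phases facing the bundle axis, point inward
and pack the core solid — there is no open channel.

*Orthosteric site*: on the wedge between the two helices opposite the
groove, a static surface notch is carved (axial sidechain beads, apolar
backbone lining).  It is present in every conformer; the reference
ligand fragment sits in it and defines the orthosteric labels.

*Allosteric (cryptic) site*: the sidechain beads of a residue window on
the first groove helix form a rigid, strongly apolar cage around an
interior point in the wedge shared with the second groove helix.  Bead
positions start on a sphere and are settled by a short deterministic
relaxation so the closed and open conformations are both clash-free.  In
the closed base state the second helix's backbone plugs the cage
interior and the cage sits flush with the surface: no pocket exists.  In
open conformers the first helix (carrying its cage) bows radially
outward by ``breathing_amplitude`` while the partner bows by a smaller
fraction, sliding the cage off its plug: a strongly apolar, enclosed
pocket opens.  The ground-truth center is the centroid of the pocket's
accessible interior (void); the labelled pocket-lining residues are all
residues an in-pocket probe could contact, i.e. with any atom within the
contact radius of the void.

Conformers add per-atom Gaussian jitter and an optional global
rigid-body displacement, emulating the 1.5–3 Å conformational drift of
relaxed MD snapshots.  Generation is bit-reproducible for a fixed seed:
a master RNG picks the open conformers and each model uses the sub-seed
``seed + model_id``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist, pdist
from scipy.spatial.transform import Rotation

from .structure_io import AtomRecord, ConformerEnsemble, ResidueKey, Structure

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "GeometryError",
    "generate_receptor",
    "generate_ensemble",
    "make_reference_ligand",
    "open_receptor",
    "accessible_volume",
]

RISE_PER_RESIDUE = 1.5    # A
HELIX_RADIUS = 2.3        # A, CA spiral radius about the helix axis
TWIST_PER_RESIDUE = 100.0  # degrees
BEAD_OFFSET = 2.8         # A, standard sidechain bead offset
FAN_COMPRESSION = 2.6     # outward cone: spiral phase divided by this
FILL_SECTOR = 42.0        # deg, spiral phases within this of inward pack the core
BREATHING_TAPER = 3.0     # residues of cos^2 taper outside the window
PARTNER_FRACTION = 0.45   # partner helix bows by this fraction of the amplitude
CAGE_RADIUS = 5.2         # A, nominal cage bead distance from the pocket anchor
CAGE_ANCHOR_RADIUS = 8.8  # A, anchor distance from the bundle axis (closed)
CAGE_ANCHOR_ANGLE = 38.0  # deg, anchor azimuth offset from the first groove helix
MIN_CONTACT = 2.5         # A, hard lower bound (closed base conformation)
LABEL_REACH = 5.0         # A, probe-contact reach used for pocket labels
ORTHO_RADIUS = 5.0        # A, residue-to-ligand radius for orthosteric labels

#: (atom_class, element, partial charge e) palette cycled along the chain.
#: The bulk surface is polar/charged; apolar material appears only at the
#: two planted sites, which is what makes them the hot spots to find.
SIDECHAIN_PALETTE = [
    ("SCP", "O", -0.25),
    ("SCN", "N", 0.45),
    ("SCP", "O", -0.25),
    ("SCN", "O", -0.45),
]

#: initial cage bead directions (azimuth, elevation; degrees) in the
#: anchor frame whose -x axis is the mouth (facing the packed core)
CAGE_DIRECTIONS = [
    (0, 0), (45, 0), (315, 0), (270, 0),
    (90, 45), (90, -45), (135, 45), (135, -45),
    (0, 50), (0, -50),
]


class GeometryError(ValueError):
    """The requested geometry is infeasible (steric overlap)."""


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic receptor/ensemble generation.

    The defaults are the study conditions used throughout the test suite
    and the acceptance run: a 7x20-residue bundle whose planted pocket is
    open in 40% of 30 conformers.  The 0.3 Å jitter is small against the
    1.5 Å reduction cutoff, while the 6.5 Å breathing amplitude puts the
    superposed open-closed CA RMSD near 1.9 Å — beyond the cutoff — so
    the two states form well-separated conformational clusters.
    """

    n_helices: int = 7
    residues_per_helix: int = 20
    bundle_radius: float = 8.5
    pocket_open_fraction: float = 0.4
    breathing_amplitude: float = 6.5
    jitter_sigma: float = 0.3
    global_motion: bool = True
    n_models: int = 30
    seed: int = 2026

    #: the cage-bearing helix and its plug partner (adjacent)
    groove_helices: tuple[int, int] = (0, 1)
    #: residue window (0-based, inclusive) providing the 10 cage beads
    groove_window: tuple[int, int] = (8, 17)

    def __post_init__(self) -> None:
        if not (0.0 <= self.pocket_open_fraction <= 1.0):
            raise ValueError("pocket_open_fraction must be in [0, 1]")
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be >= 0")
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")
        if self.n_helices < 5:
            raise ValueError("need at least 5 helices for the bundle architecture")
        lo, hi = self.groove_window
        if hi - lo + 1 != len(CAGE_DIRECTIONS):
            raise ValueError(
                f"groove_window must span {len(CAGE_DIRECTIONS)} residues"
            )
        if not (0 <= lo <= hi < self.residues_per_helix):
            raise ValueError("groove_window outside helix")
        ga, gb = self.groove_helices
        if (gb - ga) % self.n_helices != 1:
            raise ValueError("groove_helices must be adjacent (ga, ga+1)")

    # -- derived geometry -------------------------------------------------

    @property
    def half_span(self) -> float:
        return 0.5 * (self.residues_per_helix - 1) * RISE_PER_RESIDUE

    @property
    def window_mid_z(self) -> float:
        return -self.half_span + 0.5 * sum(self.groove_window) * RISE_PER_RESIDUE

    @property
    def orthosteric_helices(self) -> tuple[int, int]:
        """The wedge opposite the groove hosts the static orthosteric notch."""
        ga, _ = self.groove_helices
        return ((ga + 3) % self.n_helices, (ga + 4) % self.n_helices)

    @property
    def orthosteric_window(self) -> tuple[int, int]:
        n = self.residues_per_helix
        mid = (n - 1) // 2
        return (mid - 2, mid + 1)

    def helix_angle(self, h: int) -> float:
        return 2.0 * math.pi * h / self.n_helices

    @property
    def breathing_direction(self) -> np.ndarray:
        """Radial direction of the cage-bearing helix."""
        th = self.helix_angle(self.groove_helices[0])
        return np.array([math.cos(th), math.sin(th), 0.0])

    @property
    def cage_anchor(self) -> np.ndarray:
        """Closed-state anchor point of the cage interior."""
        ang = self.helix_angle(self.groove_helices[0]) + math.radians(CAGE_ANCHOR_ANGLE)
        return np.array(
            [
                CAGE_ANCHOR_RADIUS * math.cos(ang),
                CAGE_ANCHOR_RADIUS * math.sin(ang),
                self.window_mid_z,
            ]
        )


@dataclass
class GroundTruth:
    """Planted labels used to score pocket recovery.

    ``allosteric_center`` is the accessible-interior centroid of the open
    pocket in the base (un-jittered, un-rotated) frame;
    ``allosteric_center_closed`` is the same material point in the closed
    conformation (the cage rides the breathing helix).
    """

    orthosteric_residues: set[ResidueKey]
    allosteric_residues: set[ResidueKey]
    allosteric_center: np.ndarray
    open_models: set[int] = field(default_factory=set)
    allosteric_center_closed: np.ndarray | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "orthosteric_residues": sorted(map(list, self.orthosteric_residues)),
            "allosteric_residues": sorted(map(list, self.allosteric_residues)),
            "allosteric_center": [round(float(x), 6) for x in self.allosteric_center],
            "allosteric_center_closed": [
                round(float(x), 6) for x in self.allosteric_center_closed
            ]
            if self.allosteric_center_closed is not None
            else None,
            "open_models": sorted(self.open_models),
        }
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")


# ---------------------------------------------------------------------------
# geometry


def _helix_frame(theta: float):
    u_r = np.array([math.cos(theta), math.sin(theta), 0.0])
    u_t = np.array([-math.sin(theta), math.cos(theta), 0.0])
    u_z = np.array([0.0, 0.0, 1.0])
    return u_r, u_t, u_z


def _in_window(window: tuple[int, int], i: int) -> bool:
    return window[0] <= i <= window[1]


def _displacement_weight(spec: SyntheticSpec, i: int) -> float:
    lo, hi = spec.groove_window
    if lo <= i <= hi:
        return 1.0
    d = min(abs(i - lo), abs(i - hi))
    if d >= BREATHING_TAPER:
        return 0.0
    return math.cos(0.5 * math.pi * d / BREATHING_TAPER) ** 2


def _scaffold(spec: SyntheticSpec, amplitude: float):
    """All non-cage atoms at breathing state ``amplitude`` (0 = closed).

    Returns (coords, meta, cage_slots): ``meta`` rows are
    ``(helix, res_idx, kind, atom_class, element, charge)``; cage bead
    rows carry coords=None and their flat position is listed in
    ``cage_slots``.
    """
    ga, gb = spec.groove_helices
    oh = spec.orthosteric_helices
    ow = spec.orthosteric_window
    coords: list = []
    meta: list = []
    cage_slots: list[int] = []
    breath_dir = spec.breathing_direction
    for h in range(spec.n_helices):
        theta = spec.helix_angle(h)
        u_r, u_t, u_z = _helix_frame(theta)
        axis = spec.bundle_radius * u_r
        for i in range(spec.residues_per_helix):
            z = -spec.half_span + i * RISE_PER_RESIDUE
            alpha = math.radians(TWIST_PER_RESIDUE * i + 23.0 * h)
            wrap = math.degrees(math.atan2(math.sin(alpha), math.cos(alpha)))
            ca = axis + HELIX_RADIUS * (
                math.cos(alpha) * u_r + math.sin(alpha) * u_t
            ) + z * u_z
            in_cage = h == ga and _in_window(spec.groove_window, i)
            in_crater = h in oh and _in_window(ow, i)
            cls_ca = "CAB"
            if in_crater:
                # axial bead leaves the notch mouth open; mildly apolar
                # lining (every other bead) keeps the notch a moderate,
                # not dominant, probe site
                bead = ca + BEAD_OFFSET * np.array([0.0, 0.0, 1.0 if i % 2 else -1.0])
                if i % 2:
                    cls_b, el_b, q_b = "SCA", "C", 0.0
                else:
                    cls_b, el_b, q_b = SIDECHAIN_PALETTE[
                        (h * spec.residues_per_helix + i) % len(SIDECHAIN_PALETTE)
                    ]
            elif abs(abs(wrap) - 180.0) < FILL_SECTOR:
                # inward bead: packs the core solid
                bead = axis - (HELIX_RADIUS + BEAD_OFFSET) * u_r + z * u_z
                cls_b, el_b, q_b = SIDECHAIN_PALETTE[
                    (h * spec.residues_per_helix + i) % len(SIDECHAIN_PALETTE)
                ]
            else:
                # outward cone
                a2 = math.radians(wrap) / FAN_COMPRESSION
                e_out = math.cos(a2) * u_r + math.sin(a2) * u_t
                bead = axis + (HELIX_RADIUS + BEAD_OFFSET) * e_out + z * u_z
                cls_b, el_b, q_b = SIDECHAIN_PALETTE[
                    (h * spec.residues_per_helix + i) % len(SIDECHAIN_PALETTE)
                ]
            if amplitude > 0 and h in (ga, gb):
                w = _displacement_weight(spec, i)
                scale = amplitude if h == ga else amplitude * PARTNER_FRACTION
                disp = scale * w * (breath_dir if h == ga else u_r)
                ca = ca + disp
                bead = bead + disp
            coords.append(ca)
            meta.append((h, i, "CA", cls_ca, "C", 0.0))
            if in_cage:
                coords.append(None)
                cage_slots.append(len(coords) - 1)
                meta.append((h, i, "SC", "SCG", "C", 0.0))
            else:
                coords.append(bead)
                meta.append((h, i, "SC", cls_b, el_b, q_b))
    return coords, meta, cage_slots


def _relax_cage(spec: SyntheticSpec) -> np.ndarray:
    """Deterministic settling of the cage beads (closed-frame positions).

    Beads start on a sphere of :data:`CAGE_RADIUS` around the anchor
    (mouth sector toward the packed core left open) and are iteratively
    pushed out of clashes with the scaffold of *both* breathing states
    and with each other, while a soft radial band keeps them caged.
    """
    anchor = spec.cage_anchor
    bis = spec.helix_angle(spec.groove_helices[0]) + math.radians(CAGE_ANCHOR_ANGLE)
    xb = np.array([math.cos(bis), math.sin(bis), 0.0])
    yb = np.array([-math.sin(bis), math.cos(bis), 0.0])
    zb = np.array([0.0, 0.0, 1.0])
    beads = []
    for az, el in CAGE_DIRECTIONS:
        a, e = math.radians(az), math.radians(el)
        d = (
            math.cos(e) * math.cos(a) * xb
            + math.cos(e) * math.sin(a) * yb
            + math.sin(e) * zb
        )
        beads.append(anchor + CAGE_RADIUS * d)
    beads = np.array(beads)

    def fixed_atoms(amplitude):
        coords, _, _ = _scaffold(spec, amplitude)
        return np.array([c for c in coords if c is not None])

    closed = fixed_atoms(0.0)
    opened = fixed_atoms(spec.breathing_amplitude)
    shift = spec.breathing_amplitude * spec.breathing_direction
    for _ in range(300):
        push = np.zeros_like(beads)
        for bb, other in ((beads, closed), (beads + shift, opened)):
            d = cdist(bb, other)
            for k in range(len(beads)):
                for j in np.flatnonzero(d[k] < 2.85):
                    v = bb[k] - other[j]
                    r = max(float(np.linalg.norm(v)), 1e-6)
                    push[k] += v / r * (2.85 - r)
        for k in range(len(beads)):
            for m in range(len(beads)):
                if m == k:
                    continue
                v = beads[k] - beads[m]
                r = max(float(np.linalg.norm(v)), 1e-6)
                if r < 3.6:
                    push[k] += v / r * 0.5 * (3.6 - r)
        beads = beads + 0.5 * push
        rel = beads - anchor
        rr = np.linalg.norm(rel, axis=1)
        beads = anchor + rel / rr[:, None] * np.clip(
            rr, CAGE_RADIUS - 0.7, CAGE_RADIUS + 0.7
        )[:, None]
        if np.abs(push).max() < 1e-4:
            break
    return beads


def _base_coords(spec: SyntheticSpec, amplitude: float, cage_beads: np.ndarray):
    coords, meta, slots = _scaffold(spec, amplitude)
    shift = amplitude * spec.breathing_direction
    for k, slot in enumerate(slots):
        coords[slot] = cage_beads[k] + shift
    return np.array([np.asarray(c, dtype=float) for c in coords]), meta


def _atoms_from_geometry(coords: np.ndarray, meta) -> list[AtomRecord]:
    atoms = []
    for serial, (xyz, (h, i, kind, cls, element, charge)) in enumerate(
        zip(coords, meta), start=1
    ):
        atoms.append(
            AtomRecord(
                serial=serial,
                name="CA" if kind == "CA" else cls,
                element=element,
                residue_name="PSR",
                residue_seq=i + 1,
                chain_id=chr(ord("A") + h),
                coords=xyz,
                atom_class=cls,
                is_heavy=True,
                charge=charge,
            )
        )
    return atoms


def make_reference_ligand(spec: SyntheticSpec) -> Structure:
    """Rigid 10-atom fragment seated in the orthosteric surface notch.

    The fragment is elongated along the notch axis so that, like the
    relatively large co-crystallized ligands of real receptors, it covers
    the whole orthosteric site — the proximity classification then labels
    the full notch lining rather than a patch.  Used only to define the
    orthosteric site; it is never part of the receptor structure and
    never present during mapping.
    """
    ha, hb = spec.orthosteric_helices
    ang = 0.5 * (spec.helix_angle(ha) + spec.helix_angle(hb))
    u = np.array([math.cos(ang), math.sin(ang), 0.0])
    v = np.array([-math.sin(ang), math.cos(ang), 0.0])
    zmid = -spec.half_span + 0.5 * sum(spec.orthosteric_window) * RISE_PER_RESIDUE
    center = (spec.bundle_radius + 2.0) * u + np.array([0.0, 0.0, zmid])
    uz = np.array([0.0, 0.0, 1.0])
    # zig-zag chain spanning the notch and its lower vestibule
    # (z -7.2..+4.8) with a small tangential alternation
    body = [
        (-7.2 + 1.3333 * k) * uz + (0.9 if k % 2 == 0 else -0.9) * v
        + (0.0 if k % 2 == 0 else 0.4) * u
        for k in range(10)
    ]
    elements = ["C", "O", "C", "N", "C", "O", "C", "N", "C", "C"]
    classes = ["C2", "OH", "C2", "N", "CO", "O", "C2", "N", "C2", "C3"]
    charges = [0.10, -0.30, 0.10, -0.20, 0.30, -0.30, 0.10, -0.20, 0.20, 0.20]
    atoms = [
        AtomRecord(
            serial=i + 1,
            name=f"{elements[i]}{i + 1}",
            element=elements[i],
            residue_name="LIG",
            residue_seq=1,
            chain_id="L",
            coords=center + body[i],
            atom_class=classes[i],
            is_heavy=True,
            charge=charges[i],
            is_hetero=True,
        )
        for i in range(10)
    ]
    return Structure(0, atoms)


def _pocket_void(open_coords: np.ndarray, anchor_open: np.ndarray) -> np.ndarray:
    """Accessible-interior point set of the open cage (the pocket void)."""
    ax = np.arange(-CAGE_RADIUS, CAGE_RADIUS + 0.25, 0.5)
    grid = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), axis=-1).reshape(-1, 3)
    grid = grid[np.linalg.norm(grid, axis=1) <= CAGE_RADIUS] + anchor_open
    dist, _ = cKDTree(open_coords).query(grid)
    inside = grid[dist >= 2.0]
    if len(inside) == 0:  # pragma: no cover - geometry guard
        return anchor_open[None, :]
    return inside


def _ground_truth(spec: SyntheticSpec, cage_beads: np.ndarray) -> GroundTruth:
    closed_coords, meta = _base_coords(spec, 0.0, cage_beads)
    base = Structure(0, _atoms_from_geometry(closed_coords, meta))
    ligand = make_reference_ligand(spec)

    ortho: set[ResidueKey] = set()
    lig_xyz = ligand.coords
    for key, (lo, hi) in base.residue_index.items():
        d = np.linalg.norm(closed_coords[lo:hi, None, :] - lig_xyz[None, :, :], axis=-1)
        if d.min() <= ORTHO_RADIUS:
            ortho.add(key)

    open_coords, _ = _base_coords(spec, spec.breathing_amplitude, cage_beads)
    shift = spec.breathing_amplitude * spec.breathing_direction
    void = _pocket_void(open_coords, spec.cage_anchor + shift)
    center = void.mean(axis=0)
    # pocket-lining labels: residues an in-pocket probe can touch, i.e.
    # with any atom within the contact radius of the accessible void
    void_tree = cKDTree(void)
    allo: set[ResidueKey] = set()
    for key, (lo, hi) in base.residue_index.items():
        d, _ = void_tree.query(open_coords[lo:hi])
        if d.min() <= LABEL_REACH:
            allo.add(key)
    allo -= ortho  # disjointness invariant; the sites are far apart anyway
    return GroundTruth(
        orthosteric_residues=ortho,
        allosteric_residues=allo,
        allosteric_center=center,
        allosteric_center_closed=center - shift,
    )


def _check_feasible(coords: np.ndarray, spec: SyntheticSpec) -> None:
    dmin = pdist(coords).min()
    if dmin < MIN_CONTACT:
        raise GeometryError(
            f"infeasible spec: minimal interatomic distance {dmin:.2f} A < "
            f"{MIN_CONTACT} A (bundle_radius {spec.bundle_radius} A too small)"
        )


# ---------------------------------------------------------------------------
# public generators


def generate_receptor(spec: SyntheticSpec) -> tuple[Structure, GroundTruth]:
    """Closed base conformation of the pseudo-receptor plus ground truth.

    The cryptic cage is present but plugged by the partner helix and
    flush with the surface; the orthosteric notch is open and holds the
    (separately generated) reference ligand.
    """
    cage = _relax_cage(spec)
    coords, meta = _base_coords(spec, 0.0, cage)
    _check_feasible(coords, spec)
    structure = Structure(0, _atoms_from_geometry(coords, meta))
    return structure, _ground_truth(spec, cage)


def open_receptor(spec: SyntheticSpec) -> tuple[Structure, GroundTruth]:
    """Open-state conformation: the planted pocket is fully formed.

    Feasibility is checked on the closed base geometry; the bowed state
    may bring taper-region atoms somewhat closer (a sheared
    pseudo-structure, not a physical model).
    """
    cage = _relax_cage(spec)
    closed_coords, _ = _base_coords(spec, 0.0, cage)
    _check_feasible(closed_coords, spec)
    coords, meta = _base_coords(spec, spec.breathing_amplitude, cage)
    structure = Structure(0, _atoms_from_geometry(coords, meta))
    return structure, _ground_truth(spec, cage)


def generate_ensemble(spec: SyntheticSpec) -> tuple[ConformerEnsemble, GroundTruth]:
    """Generate ``n_models`` conformers of the base receptor.

    Open conformers (a ``round(pocket_open_fraction * n_models)``-sized
    subset chosen by the master RNG) receive the breathing displacement;
    every conformer then receives isotropic Gaussian jitter and, if
    ``global_motion``, a random rigid-body rotation+translation.
    """
    cage = _relax_cage(spec)
    closed_coords, meta = _base_coords(spec, 0.0, cage)
    _check_feasible(closed_coords, spec)
    open_coords, _ = _base_coords(spec, spec.breathing_amplitude, cage)
    truth = _ground_truth(spec, cage)

    n_open = int(round(spec.pocket_open_fraction * spec.n_models))
    master = np.random.default_rng(spec.seed)
    truth.open_models = {int(m) for m in master.permutation(spec.n_models)[:n_open]}

    models = []
    for m in range(spec.n_models):
        rng = np.random.default_rng(spec.seed + m + 1)
        coords = (open_coords if m in truth.open_models else closed_coords).copy()
        if spec.jitter_sigma > 0:
            coords = coords + rng.normal(0.0, spec.jitter_sigma, coords.shape)
        if spec.global_motion:
            quat = rng.normal(size=4)
            rot = Rotation.from_quat(quat / np.linalg.norm(quat))
            shift = rng.uniform(-3.0, 3.0, 3)
            coords = rot.apply(coords) + shift
        models.append(Structure(m, _atoms_from_geometry(coords, meta)))

    ensemble = ConformerEnsemble(models=models)
    ensemble.alignment_selection = [
        i for i, a in enumerate(models[0].atoms) if a.name == "CA"
    ]
    return ensemble, truth


def accessible_volume(
    structure: Structure,
    center: np.ndarray,
    radius: float = 4.0,
    probe_clearance: float = 2.0,
    spacing: float = 0.5,
) -> float:
    """Grid-counted accessible volume (A^3) inside a sphere around *center*.

    A grid point counts as accessible when it is at least
    ``probe_clearance`` from every receptor atom.  Used to verify that
    the planted pocket's enclosing-sphere volume is larger in open
    conformers (measured at the open-state center) than in closed ones
    (measured at the same material point, ``allosteric_center_closed``).
    """
    center = np.asarray(center, dtype=float)
    ax = np.arange(-radius, radius + spacing / 2, spacing)
    grid = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), axis=-1).reshape(-1, 3)
    grid = grid[np.linalg.norm(grid, axis=1) <= radius] + center
    tree = cKDTree(structure.coords)
    dist, _ = tree.query(grid, k=1)
    return float(np.sum(dist >= probe_clearance) * spacing**3)
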