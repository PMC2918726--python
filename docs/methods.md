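# Methods

`ensmap` reimplements, at desk scale, an ensemble fragment-mapping
analysis for finding non-orthosteric (putative allosteric) binding hot
spots on receptor structures.  The pipeline has four stages: reduction
of a conformer ensemble to representative structures, multi-probe
hot-spot mapping of each representative, aggregation of probe clusters
into ranked consensus sites, and an ensemble-level per-residue
probe-interaction statistic with site grouping.  This note records the
models, the tunable parameters, the numerical choices, and what the
synthetic test system does and does not show.

## Conformer-ensemble reduction

Conformers are superposed by least-squares rigid-body fitting (Kabsch,
via `scipy`'s `Rotation.align_vectors`) on a common atom selection —
all backbone `CA` beads by default, or any expression in the package's
selection grammar.  The all-pairs RMSD matrix over the same selection
feeds GROMOS-style neighbor clustering (Daura et al.): the structure
with the most neighbors within the cutoff becomes a cluster center and
is removed together with its neighbors, repeating until none remain.
Defaults: cutoff 1.5 Å, top 15 clusters retained; the cluster center
(max-neighbor structure) is the representative.  Ties — in neighbor
counts, cluster sizes, and everywhere else in the package — break
toward the lowest model id, making the reduction deterministic under
relabeling.  The neighbor relation is inclusive (RMSD ≤ cutoff).  The
report records the percentage of conformers covered by the retained
clusters.

## Probe library

Sixteen rigid organic fragments (ethanol, isopropanol, isobutanol,
acetone, acetaldehyde, dimethyl ether, cyclohexane, ethane,
acetonitrile, urea, methylamine, phenol, benzaldehyde, benzene,
acetamide, N,N-dimethylformamide) are built once from SMILES with RDKit
(ETKDG embedding, fixed seed; MMFF94 relaxation) and reduced to heavy
atoms united-atom style: each hydrogen's Gasteiger charge is folded
into its parent heavy atom, and the heavy atom's nonbonded class
encodes its hydrogen count.  Body frames are centered on the heavy-atom
centroid.  Probe geometries are part of the protocol and deterministic.

## Energy model

Probe–receptor scoring is a transparent stand-in for empirical hot-spot
scoring functions, not a re-derivation of one:

* Lennard-Jones 12-6 on a small internal atom-class table
  (united-atom-scale σ, ε; Lorentz–Berthelot combining), truncated at
  the nonbonded cutoff (8 Å) and capped per pair at +100 kJ/mol;
* Coulomb electrostatics with a distance-dependent dielectric
  ε(r) = 4r (pair energy `k·q₁q₂ / 4r²`), same truncation, with the
  distance clamped at 2 Å (inside any vdW contact, so the clamp only
  affects clashed pairs);
* no solvation term.

Units are Å, kJ/mol and elementary charges throughout.

### Energy grids

Per probe-atom class, the summed capped LJ energy is precomputed on a
grid, plus one electrostatic-potential grid (per unit probe charge).
Candidate probe translations live on a 0.8 Å lattice; interpolation
uses a 5× finer sub-grid (0.16 Å) with trilinear interpolation, which
bounds the representation error of retained attractive poses below
1 kJ/mol — plain trilinear at 0.8 Å is several kJ/mol off near the
steep LJ wall, so the lattice (a protocol constant) and the
interpolation resolution (an implementation device) are deliberately
decoupled.  The box extends one nonbonded cutoff beyond every receptor
heavy atom; outside it the field is exactly zero, and out-of-box probe
atoms contribute zero.  Grids are stored in float32 (≈0.9 GB for the
default synthetic receptor, held only while one structure is mapped).

### Exhaustive sampling

Each probe is scored at every rotation of a quasi-uniform quaternion
set (scrambled Halton sequence + uniform-quaternion mapping, seeded
from the config; 500 orientations by library default) times every
candidate lattice translation.  The `poses_retained` = 2000
lowest-energy poses are kept, sorted ascending, ties broken by
(rotation index, grid index).  Two exact devices keep this tractable:

* far lattice points (beyond cutoff + probe radius) have exactly zero
  energy and are materialized only if needed to fill the retained set;
* a sound branch-and-bound: a pose is abandoned once its partial energy
  plus the remaining atoms' global field lower bound exceeds the
  current 2000th-best energy — it provably cannot be retained.

An optional translation pre-filter (`sample_shell`) restricts
candidates to lattice points whose distance to the receptor lies in a
band; the library default is off (exact enumeration, used by the oracle
tests), while the pipeline's operating point uses (2.25, 6.0) Å — on
receptor-sized systems far more than 2000 strongly negative candidates
exist inside the band, so the retained set is unchanged.

### Minimization and clustering

Retained poses are locally minimized as rigid bodies (6 DOF) against
the direct pair-sum energy: batched gradient descent (analytic LJ +
Coulomb gradients; capped/clamped pairs contribute zero gradient) with
per-pose backtracking, so the accepted energy sequence never increases;
iteration is bounded (80 by default) and non-convergence returns the
best pose so far, flagged.  Minimized poses are clustered greedily in
energy order: the lowest-energy unassigned pose seeds a cluster and
collects all unassigned poses within 3 Å probe-atom RMSD (receptor
frame, no re-superposition — poses are placements, not conformations;
atom correspondence is by index, so symmetric probes such as benzene
measure placement, not graph, distance).  The six clusters of lowest
mean energy are retained per probe.

### Consensus sites

Retained clusters of all probes are aggregated by single linkage on
center-pose centroids at 4 Å.  Consensus sites are ranked by the number
of member probe clusters (ties: lower aggregate mean energy, then the
lexicographically first member probe name); the 10 largest are
reported, with the center of mass defined as the unweighted mean of
member cluster centroids.

## Residue profiling

An interaction is counted whenever a probe heavy atom of a
consensus-site pose lies within 5 Å (inclusive) of a protein heavy atom
— counting is at the atom-pair level, so one probe atom near three
atoms of a residue contributes three counts.  Counts are summed over
all mapped representatives and expressed as percentages of the grand
total; residues are ranked descending (ties: lower residue number) and
the top 40 with nonzero counts analyzed further.  Residues with any
heavy atom within 5 Å of the reference ligand (measured in the
reference structure) are classified orthosteric.

Non-orthosteric top residues are grouped into candidate sites by
linkage with two conditions: minimal inter-residue heavy-atom distance
≤ 5 Å in the reference structure, *and* the sets of poses contacting
the two residues overlap with Jaccard ≥ 0.2.  The spatial condition
alone percolates at desk scale — on a compact 140-residue bundle almost
every pair of surface sites is bridged by chains of spatially adjacent
contacted residues — while a candidate site is really a set of residues
together with the probes they bind; requiring shared probes splits
spatially fused but independently occupied regions.  Without pose
information the grouping falls back to the purely spatial rule.  Sites
are numbered by descending summed percentage, and every pose contacting
a site residue is attached to it (contacts evaluated in each pose's own
conformer when poses come from several representatives).

For synthetic runs the classification/grouping reference is the closed
base conformation — the analogue of an experimental structure, and the
frame the reference ligand is defined in.  For file-based runs it is
the first ensemble model, and a supplied ligand must share its frame.

## Synthetic test system

The generator emulates the essential phenomenology of a receptor MD
ensemble: a compact pseudo-receptor with a constitutive (orthosteric)
pocket and a cryptic (allosteric) pocket that exists only in a subset
of conformers.

Seven pseudo-helices (20 residues each by default; backbone bead +
sidechain bead per residue, 280 atoms total) stand on a ring of radius
8.5 Å.  Sidechain beads whose helical spiral phase faces the bundle
axis point inward and pack the core solid; the rest fan over the outer
surface.  The bulk surface palette is polar/charged — apolar material
appears only at the two planted sites, which is what makes them the
dominant hot spots.

*Orthosteric notch*: on the wedge between the two helices opposite the
groove, sidechain beads of a four-residue window are laid axially,
leaving an open surface notch (alternating mildly apolar lining).  A
rigid ten-atom reference fragment spans the notch; residues within 5 Å
of it are the orthosteric labels.

*Cryptic pocket*: the ten sidechain beads of a residue window on one
groove helix form a rigid cage of strongly apolar beads around an
anchor in the wedge shared with the adjacent helix.  Initial cage
directions leave a mouth toward the packed core; positions are settled
by a short deterministic push-out-of-clash relaxation against both
breathing states.  Closed: the partner helix's backbone plugs the
interior and the cage sits flush with the surface — no pocket.  Open:
the cage-bearing helix bows radially outward by the breathing
amplitude (6.5 Å, cos²-tapered along the helix) and the partner by 45%
of it, sliding the cage off its plug; a strongly apolar enclosed pocket
appears.  The ground truth records the centroid of the pocket's
accessible interior (void) and, as pocket-lining labels, every residue
with an atom within the 5 Å contact radius of that void.

Ensemble generation: a seed-determined subset of conformers
(`pocket_open_fraction`, default 0.4 of 30 models) receives the
breathing displacement; all conformers then receive isotropic Gaussian
jitter (0.3 Å) and a random rigid-body rotation + translation.  The
open-closed CA RMSD after superposition is ≈1.9 Å — past the 1.5 Å
reduction cutoff — so reduction recovers exactly the two conformational
states; the jitter scale keeps within-state RMSD ≈0.4 Å.  Everything is
bit-reproducible for a fixed seed (master RNG for the open subset;
per-model sub-seeds `seed + model_id`).

What the generator does *not* emulate: real protein geometry and
chemistry, solvent/membrane environments, physically continuous
dynamics, and gradual (rather than two-state) pocket formation.
Passing recovery tests therefore demonstrate that the pipeline detects
an enclosed, strongly apolar, conformation-dependent pocket against a
polar background at desk scale — not performance on real MD ensembles.

## Operating point and problem sizes

The pipeline's default mapping configuration uses the protocol
constants (16 probes, 2000 poses retained, 6 clusters per probe, 10
consensus sites, 1.5 Å/15 reduction, 5 Å/40 profiling) with two
desk-scale sampling choices: 200 rotations (the library default of 500
is exposed in the config; orientation resolution beyond ~40° changes
little for bead receptors) and the (2.25, 6.0) Å translation shell.
One representative maps in roughly 1–2 minutes on a single CPU; the
default run reduces 30 conformers to 2 representatives, so a full
pipeline completes in a few minutes.

## Conventions and edge cases

* Multi-model PDB is the ensemble interchange format.  Residue key =
  (chain, residue number, insertion code); atom indices are internal
  0-based half-open ranges; PDB `MODEL` serials are written 1-based and
  do not preserve in-memory model ids.
* Partial charges of package-generated pseudo-structures ride in the
  B-factor column, palette-quantized to 0.01 e so the 2-decimal field
  is lossless; for foreign PDBs that column is a temperature factor and
  energy evaluation is not meaningful.
* Alternate locations: highest occupancy wins, ties to the first
  encountered.
* Degenerate superposition selections (collinear/coincident, or fewer
  than three atoms) raise; empty atom selections warn and return an
  empty list.
* A grand contact total of zero yields all-zero percentages with a
  warning; an empty pose list yields an all-zero count map.
* The reported minimized pose energy is the direct pair-sum energy; the
  descent contract is relative to the input pose's direct energy.

## Known limitations

* The scoring function is a generic LJ+Coulomb stand-in; numerical
  agreement with any published empirical mapping server is neither
  expected nor claimed.
* Pose-cluster RMSD uses atom-index correspondence, which overestimates
  distances between symmetry-equivalent placements of symmetric probes.
* The closed conformation of the synthetic receptor still shows faint
  probe affinity around the plugged pocket's rim; single-structure
  control profiling can brush a few pocket-lining residues, which is
  visible as a small but nonzero closed-structure Jaccard overlap.
* Recovery margins are validated at the default study conditions and
  fixed seeds; they are expected, but not guaranteed, to hold for every
  seed.
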