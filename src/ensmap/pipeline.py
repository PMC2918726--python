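"""End-to-end pipeline: synth -> reduce -> map -> profile.

One seed controls the whole run: the synthetic generator uses it
directly and the mapping stage derives its rotation-set seed from it
(fixed offset), so two runs with equal config and seed produce
byte-identical output tables.

Stage outputs written to the run directory:

* ``ensemble.pdb``, ``ligand.pdb``, ``ground_truth.json`` (synthetic runs)
* ``reduction.tsv`` — cluster id, size, center model, occupancy
* ``representatives.pdb`` — multi-model PDB of the retained centers
* ``mapped_rep<i>.pdb`` — each representative with its consensus-site
  probe poses, plus ``consensus_sites.tsv``
* ``residue_table.tsv`` — rank, residue, raw count, percentage,
  orthosteric flag, site id (the machine-readable residue ranking)
* ``sites.tsv`` — site summaries
* ``run_metadata.json`` — config echo, seed, config hash, versions
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .ensemble_reduction import (
    ReductionReport,
    gromos_cluster,
    pairwise_rmsd_matrix,
    select_representatives,
)
from .probe_mapping import MappingConfig, MappingResult, map_structure
from .residue_profiling import (
    ProfilingConfig,
    ResidueProfile,
    SiteGroup,
    aggregate_profiles,
    classify_orthosteric,
    count_contacts,
    group_sites,
    pose_contact_sets,
    select_top_n,
)
from .structure_io import (
    ConformerEnsemble,
    Structure,
    read_pdb_models,
    select_atoms,
    write_ensemble_pdb,
    write_pdb_with_probes,
)
from .synthetic_data import (
    GroundTruth,
    SyntheticSpec,
    generate_ensemble,
    generate_receptor,
    make_reference_ligand,
)

__all__ = [
    "ReductionConfig",
    "PipelineConfig",
    "RunReport",
    "run_pipeline",
    "frame_count",
    "load_config",
    "save_config",
]

logger = logging.getLogger("ensmap")

MAPPING_SEED_OFFSET = 101  # mapping rotation-set seed = pipeline seed + offset


@dataclass
class ReductionConfig:
    cutoff: float = 1.5   # A, neighbor cutoff of the Daura clustering
    top_k: int = 15       # representatives retained
    selection: str | None = None  # selection expression; None = all CA heavy

    def __post_init__(self) -> None:
        if self.cutoff <= 0 or self.top_k < 1:
            raise ValueError("invalid reduction config")


def _default_mapping() -> MappingConfig:
    """Pipeline operating point: protocol constants at library defaults,
    with the desk-scale sampling devices enabled (translation shell,
    200-orientation rotation set)."""
    return MappingConfig(rotation_count=200, sample_shell=(2.25, 6.0))


@dataclass
class PipelineConfig:
    seed: int = 7
    synthetic: SyntheticSpec | None = field(default_factory=SyntheticSpec)
    ensemble_path: str | None = None  # used when synthetic is None
    ligand_path: str | None = None
    reduction: ReductionConfig = field(default_factory=ReductionConfig)
    mapping: MappingConfig = field(default_factory=_default_mapping)
    profiling: ProfilingConfig = field(default_factory=ProfilingConfig)

    def __post_init__(self) -> None:
        if self.synthetic is None and self.ensemble_path is None:
            raise ValueError("either a synthetic spec or an ensemble path is required")

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.mapping.sample_shell is not None:
            d["mapping"]["sample_shell"] = list(self.mapping.sample_shell)
        if self.synthetic is not None:
            d["synthetic"]["groove_helices"] = list(self.synthetic.groove_helices)
            d["synthetic"]["groove_window"] = list(self.synthetic.groove_window)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        syn = d.get("synthetic")
        if syn is not None:
            syn = dict(syn)
            for key in ("groove_helices", "groove_window"):
                if key in syn:
                    syn[key] = tuple(syn[key])
            d["synthetic"] = SyntheticSpec(**syn)
        if d.get("reduction") is not None:
            d["reduction"] = ReductionConfig(**d["reduction"])
        if d.get("mapping") is not None:
            m = dict(d["mapping"])
            if m.get("sample_shell") is not None:
                m["sample_shell"] = tuple(m["sample_shell"])
            d["mapping"] = MappingConfig(**m)
        if d.get("profiling") is not None:
            d["profiling"] = ProfilingConfig(**d["profiling"])
        return cls(**d)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def save_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def load_config(path: str | Path) -> PipelineConfig:
    return PipelineConfig.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class RunReport:
    config: PipelineConfig
    reduction: ReductionReport
    mapping_results: list[MappingResult]
    profiles: list[ResidueProfile]
    top_profiles: list[ResidueProfile]
    sites: list[SiteGroup]
    ground_truth: GroundTruth | None
    out_dir: Path
    representatives: ConformerEnsemble | None = None


# ---------------------------------------------------------------------------


def frame_count(total_duration_ns: float, interval_ps: float) -> int:
    """Number of saved frames for a trajectory sampled at fixed intervals.

    ``total_duration_ns`` is in nanoseconds, ``interval_ps`` in
    picoseconds.  A duration that is not an integer multiple of the
    interval is floored with a warning.
    """
    if total_duration_ns <= 0 or interval_ps <= 0:
        raise ValueError("duration and interval must be positive")
    frames = total_duration_ns * 1000.0 / interval_ps
    rounded = round(frames)
    if abs(frames - rounded) < 1e-9:
        return int(rounded)
    warnings.warn("duration is not a multiple of the saving interval; flooring")
    return int(np.floor(frames))


# ---------------------------------------------------------------------------


def _write_reduction_tsv(report: ReductionReport, path: Path) -> None:
    lines = ["cluster\tsize\tcenter_model\tmembers"]
    for i, c in enumerate(report.clusters, start=1):
        members = ",".join(str(m) for m in c.member_models)
        lines.append(f"{i}\t{c.size}\t{c.center_model}\t{members}")
    lines.append(f"# cutoff_A\t{report.cutoff}")
    lines.append(f"# top_k\t{report.k}")
    lines.append(f"# occupancy_top_k_percent\t{report.occupancy_of_top_k:.4f}")
    path.write_text("\n".join(lines) + "\n")


def _write_cs_tsv(results: list[MappingResult], path: Path) -> None:
    lines = ["structure\trank\tsize\tmean_energy_kJ_mol\tprobes\tcom_x\tcom_y\tcom_z"]
    for res in results:
        for s in res.consensus_sites:
            com = s.center_of_mass
            lines.append(
                f"{res.structure_id}\t{s.rank}\t{s.size}\t{s.mean_energy:.4f}\t"
                f"{'|'.join(s.probe_names())}\t{com[0]:.3f}\t{com[1]:.3f}\t{com[2]:.3f}"
            )
    path.write_text("\n".join(lines) + "\n")


def _write_residue_tsv(
    profiles: list[ResidueProfile], site_of: dict, path: Path
) -> None:
    lines = ["rank\tchain\tresid\traw_count\tpercentage\torthosteric\tsite_id"]
    for p in profiles:
        chain, seq, _ = p.residue_key
        sid = site_of.get(p.residue_key, 0)
        lines.append(
            f"{p.rank}\t{chain}\t{seq}\t{p.raw_count}\t{p.percentage:.6f}\t"
            f"{int(p.orthosteric)}\t{sid}"
        )
    path.write_text("\n".join(lines) + "\n")


def _write_sites_tsv(sites: list[SiteGroup], path: Path) -> None:
    lines = ["site_id\tn_residues\tsummed_percentage\tn_probes\tresidues"]
    for s in sites:
        residues = ",".join(f"{c}{n}" for c, n, _ in s.residues)
        lines.append(
            f"{s.site_id}\t{len(s.residues)}\t{s.summed_percentage:.6f}\t"
            f"{len(s.member_probes)}\t{residues}"
        )
    path.write_text("\n".join(lines) + "\n")


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> RunReport:
    """Run the full analysis and write all stage outputs to ``out_dir``.

    Deterministic for a fixed config and seed.  Stage failures raise with
    the stage name; outputs written so far are left in place.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth: GroundTruth | None = None
    ligand: Structure | None = None
    reference: Structure | None = None

    # --- inputs ---------------------------------------------------------
    if config.synthetic is not None:
        spec = dataclasses.replace(config.synthetic, seed=config.seed)
        logger.info("synth: generating ensemble (%d models)", spec.n_models)
        ensemble, truth = generate_ensemble(spec)
        ligand = make_reference_ligand(spec)
        # classification/grouping reference: the base (closed) receptor,
        # the analogue of the experimental structure the ligand sits in
        reference, _ = generate_receptor(spec)
        write_ensemble_pdb(ensemble, out / "ensemble.pdb")
        write_ensemble_pdb(
            ConformerEnsemble(models=[ligand]), out / "ligand.pdb"
        )
        truth.to_json(out / "ground_truth.json")
    else:
        logger.info("loading ensemble from %s", config.ensemble_path)
        ensemble = read_pdb_models(config.ensemble_path)
        if config.ligand_path:
            ligand = read_pdb_models(config.ligand_path).models[0]
        reference = ensemble.models[0]

    if config.reduction.selection:
        ensemble.alignment_selection = select_atoms(
            ensemble.models[0], config.reduction.selection
        )

    # --- reduction ------------------------------------------------------
    logger.info("reduce: clustering %d conformers", len(ensemble))
    matrix = pairwise_rmsd_matrix(ensemble)
    clusters = gromos_cluster(matrix, config.reduction.cutoff)
    if len(clusters) < config.reduction.top_k:
        logger.warning(
            "only %d clusters found (top_k=%d); using all",
            len(clusters),
            config.reduction.top_k,
        )
    representatives, report = select_representatives(
        clusters, ensemble, k=config.reduction.top_k, cutoff=config.reduction.cutoff
    )
    _write_reduction_tsv(report, out / "reduction.tsv")
    write_ensemble_pdb(representatives, out / "representatives.pdb")

    # --- mapping --------------------------------------------------------
    mapping_config = dataclasses.replace(
        config.mapping, seed=config.seed + MAPPING_SEED_OFFSET
    )
    mapping_results = []
    for i, rep in enumerate(representatives.models):
        logger.info(
            "map: representative %d/%d (model %d)",
            i + 1,
            len(representatives.models),
            rep.model_id,
        )
        result = map_structure(rep, mapping_config)
        mapping_results.append(result)
        write_pdb_with_probes(
            rep, result.consensus_sites, out / f"mapped_rep{i}.pdb"
        )
    _write_cs_tsv(mapping_results, out / "consensus_sites.tsv")

    # --- profiling ------------------------------------------------------
    logger.info("profile: aggregating contacts over %d conformers", len(mapping_results))
    per_structure_counts = []
    all_poses = []
    all_contacts = []
    for rep, result in zip(representatives.models, mapping_results):
        poses = result.cs_poses()
        per_structure_counts.append(count_contacts(rep, poses, config.profiling))
        all_poses.extend(poses)
        all_contacts.extend(pose_contact_sets(rep, poses, config.profiling))
    profiles = aggregate_profiles(per_structure_counts)
    profiles = classify_orthosteric(profiles, reference, ligand, config.profiling)
    top = select_top_n(profiles, config.profiling)
    sites = group_sites(
        top, reference, all_poses, config.profiling, pose_contacts=all_contacts
    )

    site_of = {key: g.site_id for g in sites for key in g.residues}
    _write_residue_tsv(top, site_of, out / "residue_table.tsv")
    _write_sites_tsv(sites, out / "sites.tsv")

    metadata = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "n_models": len(ensemble),
        "n_representatives": len(representatives.models),
        "occupancy_top_k_percent": round(report.occupancy_of_top_k, 4),
        "cs_counts": [len(r.consensus_sites) for r in mapping_results],
        "n_site_groups": len(sites),
    }
    (out / "run_metadata.json").write_text(json.dumps(metadata, indent=1) + "\n")

    return RunReport(
        config=config,
        reduction=report,
        mapping_results=mapping_results,
        profiles=profiles,
        top_profiles=top,
        sites=sites,
        ground_truth=truth,
        out_dir=out,
        representatives=representatives,
    )
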