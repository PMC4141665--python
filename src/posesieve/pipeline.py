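"""Config-driven end-to-end runs.

Executes the full post-docking assessment on user or fixture data:
receptor-ensemble superposition and cavity-fingerprint clustering, ligand
torsion clustering, pose intake, the clash/minimise/GBSA/window/PBSA/mode
sieve, and per-representative residue-pair decomposition and probability
maps. Every stage logs in/out counts; the run directory receives TSV
ledgers, a plain-text report and a reproducibility manifest (config hash,
package version, seed). Outputs carry no timestamps, so identical config
and inputs give byte-identical results.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .binding import contact_probability_maps, pairwise_interaction_decomposition, sieve_poses
from .binding import _assemble_complex  # shared complex assembly
from .cavities import (
    build_grid_catalogue,
    cluster_cavities,
    compute_cavity_fingerprint,
    fingerprint_distance_matrix,
    select_cavity_representatives,
)
from .clashes import DockedPose
from .conformers import cluster_torsions, extract_torsions
from .core import (
    ConformationEnsemble,
    apply_parameters,
    read_parameter_table,
    read_structure,
    superpose,
)
from .solvent import GridSpec, MembraneModel

__all__ = ["RunConfig", "run_full_pipeline"]


@dataclass
class RunConfig:
    """Full run configuration; defaults are the framework's standard
    protocol values (2.4/4.0 A fingerprint radii, 0.3 cut, 45/10 deg torsion
    radii, 0.5 overlap / 5 clashes, 27 kcal/mol window, 5 A mode radius,
    6.5 A contacts, 3.5 A / 90 deg hydrogen bonds, the membrane and PB
    grid blocks)."""

    receptor_ensemble: str = ""
    ligand_ensemble: str = ""
    poses: str = ""
    parameter_table: str = ""
    output_dir: str = "run_out"
    seed: int = 0

    superpose_selection: str = "name CA"
    grid_origin: tuple[float, float, float] = (-25.0, -25.0, -30.0)
    grid_dims: tuple[int, int, int] = (18, 18, 22)
    grid_spacing: float = 2.8
    exclusion_radius: float = 2.4
    inclusion_radius: float = 4.0
    inclusion_region: list = field(default_factory=lambda: [[0.0, 0.0, float(z)] for z in range(-12, 13, 2)])
    cavity_cut: float = 0.3
    cavity_linkage: str = "average"

    dihedrals: list = field(default_factory=list)  # [[resid, name] x 4] per angle
    torsion_radius: float = 45.0
    torsion_max_error: float = 10.0

    max_clashes: int = 5
    overlap_fraction: float = 0.5
    minimize_steps: int = 100
    minimize_dielectric: float = 4.0
    energy_window: float = 27.0
    mode_radius: float = 5.0

    membrane: dict = field(default_factory=dict)  # MembraneModel overrides
    pb_grid: dict | None = None  # {"n_points": ..., "spacing": ..., "center": ...}; None = GBSA only
    sasa_points: int = 960
    pb_tol: float = 1e-4

    contact_threshold: float = 6.5
    hbond_dmax: float = 3.5
    hbond_angle_min: float = 90.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @property
    def config_hash(self) -> str:
        # the hash captures inputs and scientific parameters, not where
        # the outputs land
        data = asdict(self)
        data.pop("output_dir")
        return hashlib.sha256(yaml.safe_dump(data, sort_keys=True).encode()).hexdigest()[:16]


def _resolve_dihedrals(topology, defs) -> list[tuple[int, int, int, int]]:
    quads = []
    for quad in defs:
        idxs = []
        for resid, name in quad:
            hit = np.nonzero((topology.residue_ids == int(resid)) & (topology.names == name))[0]
            if hit.size != 1:
                raise KeyError(f"dihedral atom (resid {resid}, name {name}) not found")
            idxs.append(int(hit[0]))
        quads.append(tuple(idxs))
    return quads


def run_full_pipeline(config: RunConfig) -> dict:
    """Execute the full flowchart; returns the machine-readable report."""
    for key in ("receptor_ensemble", "ligand_ensemble", "poses", "parameter_table"):
        path = getattr(config, key)
        if not path or not Path(path).exists():
            raise FileNotFoundError(f"config key {key!r}: missing input {path!r}")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}, "config_hash": config.config_hash, "seed": config.seed}
    table = read_parameter_table(config.parameter_table)

    # --- stage 1: receptor ensemble, superposition, cavity clustering ---
    rec_ens = read_structure(config.receptor_ensemble, model_policy="all")
    if isinstance(rec_ens, ConformationEnsemble):
        ref = rec_ens.structure(0)
        sel = ref.select(config.superpose_selection)
        aligned = []
        for i in range(rec_ens.n_frames):
            frame = rec_ens.structure(i)
            fitted, _ = superpose(frame, ref, frame.select(config.superpose_selection), sel)
            aligned.append(fitted.coords)
        rec_ens = ConformationEnsemble(rec_ens.topology, np.array(aligned), rec_ens.frame_labels)
    else:
        rec_ens = ConformationEnsemble(rec_ens, rec_ens.coords[None], [rec_ens.frame_label])
    catalogue = build_grid_catalogue(config.grid_origin, config.grid_dims, config.grid_spacing)
    region = np.asarray(config.inclusion_region, dtype=float)
    fps = [
        compute_cavity_fingerprint(
            rec_ens.structure(i), catalogue, region,
            config.exclusion_radius, config.inclusion_radius,
        )
        for i in range(rec_ens.n_frames)
    ]
    if len(fps) >= 2:
        dmat = fingerprint_distance_matrix(fps)
        assignment = cluster_cavities(dmat, cut=config.cavity_cut, linkage=config.cavity_linkage)
        reps = select_cavity_representatives(assignment, fps)
        dmat.to_csv(out / "cavity_distances.csv")
    else:
        reps = {1: fps[0].frame_label}
    label_to_frame = {rec_ens.frame_labels[i]: i for i in range(rec_ens.n_frames)}
    receptor_frames = {
        lab: apply_parameters(rec_ens.structure(label_to_frame[lab]), table)
        for lab in reps.values()
    }
    report["stages"]["cavities"] = {
        "frames": rec_ens.n_frames,
        "clusters": len(reps),
        "representatives": sorted(reps.values()),
    }

    # --- stage 2: ligand torsion clustering ---
    lig_ens = read_structure(config.ligand_ensemble, model_policy="all")
    if not isinstance(lig_ens, ConformationEnsemble):
        lig_ens = ConformationEnsemble(lig_ens, lig_ens.coords[None], [lig_ens.frame_label])
    if config.dihedrals:
        quads = _resolve_dihedrals(lig_ens.topology, config.dihedrals)
        vectors = extract_torsions(lig_ens, quads)
        tors = cluster_torsions(
            vectors, radius=config.torsion_radius, max_error=config.torsion_max_error
        )
        n_torsion_clusters = tors.assignment.n_clusters
        rows = ["frame\tcluster"] + [
            f"{l}\t{c}" for l, c in zip(tors.assignment.labels, tors.assignment.cluster_ids)
        ]
        (out / "torsion_clusters.tsv").write_text("\n".join(rows) + "\n")
    else:
        n_torsion_clusters = 0
    report["stages"]["torsions"] = {
        "frames": lig_ens.n_frames, "clusters": n_torsion_clusters
    }

    # --- stage 3: poses in ---
    pose_input = read_structure(config.poses, model_policy="all")
    if not isinstance(pose_input, ConformationEnsemble):
        pose_input = ConformationEnsemble(pose_input, pose_input.coords[None], [pose_input.frame_label])
    default_receptor = sorted(receptor_frames)[0]
    poses = [
        DockedPose(
            ligand=apply_parameters(pose_input.structure(i), table),
            receptor_label=default_receptor,
            pose_id=i,
        )
        for i in range(pose_input.n_frames)
    ]
    report["stages"]["poses"] = {"count": len(poses)}

    # --- stage 4: the sieve ---
    membrane = MembraneModel(**config.membrane)
    grid = GridSpec(**config.pb_grid) if config.pb_grid else None
    sieved = sieve_poses(
        receptor_frames,
        poses,
        m=membrane,
        g=grid,
        max_clashes=config.max_clashes,
        overlap_fraction=config.overlap_fraction,
        minimize_steps=config.minimize_steps,
        minimize_dielectric=config.minimize_dielectric,
        window=config.energy_window,
        mode_radius=config.mode_radius,
        sasa_points=config.sasa_points,
        pb_tol=config.pb_tol,
        run_pbsa=grid is not None,
    )
    sieved.ledger.to_csv(out / "sieve_ledger.tsv", sep="\t", index=False)
    report["stages"]["sieve"] = dict(sieved.stage_counts)

    # --- stage 5: decomposition + maps on representatives ---
    rep_summaries = {}
    by_id = {p.pose_id: p for p in sieved.kept}
    for mode_id, pose_id in sorted(sieved.representatives.items()):
        pose = by_id[pose_id]
        receptor = receptor_frames[pose.receptor_label]
        complex_, rsel, lsel = _assemble_complex(receptor, pose.ligand)
        decomposition = pairwise_interaction_decomposition(
            complex_, rsel, lsel, membrane, sasa_points=config.sasa_points
        )
        decomposition.to_tsv(out / f"decomposition_mode{mode_id}.tsv")
        single = ConformationEnsemble(complex_, complex_.coords[None], [f"mode{mode_id}"])
        maps = contact_probability_maps(
            single,
            receptor_residues=list(receptor.residue_index),
            ligand_residues=[(str(c), int(r)) for c, r in pose.ligand.residue_index],
            threshold=config.contact_threshold,
        )
        for key, frame in maps.to_frames().items():
            frame.to_csv(out / f"contacts_mode{mode_id}_{key}.csv")
        top = decomposition.sorted_by_magnitude().head(3)
        rep_summaries[str(mode_id)] = {
            "pose_id": pose_id,
            "dg_gbsa": round(sieved.scores[pose_id].dg_gbsa, 4),
            "dg_pbsa": round(sieved.scores[pose_id].dg_pbsa, 4),
            "top_pairs": [
                f"{r.receptor_residue}-{r.ligand_residue}: {r.total:.2f}"
                for r in top.itertuples()
            ],
        }
    report["stages"]["analysis"] = rep_summaries

    manifest = {
        "config_hash": config.config_hash,
        "posesieve_version": __version__,
        "seed": config.seed,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    (out / "config.yaml").write_text(config.to_yaml())
    return report
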