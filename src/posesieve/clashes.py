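"""Steric clash filter for docked poses.

A receptor-ligand atom pair clashes when the two spheres overlap by more
than a fraction of the sum of their radii: with overlap fraction f
(default 0.5), atoms i, j clash iff

    d(i, j) < (1 - f) * (r_i + r_j),

i.e. the overlap depth r_i + r_j - d exceeds f * (r_i + r_j). Poses with
more than ``max_clashes`` (default 5) such pairs are rejected. Radii are
the per-atom solvation radii; hydrogens are ignored; the comparison is a
strict inequality (d exactly at threshold is not a clash).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .core import MolecularStructure, ParameterError

__all__ = [
    "DockedPose",
    "ClashReport",
    "count_clashes",
    "filter_poses",
    "write_clash_reports",
]

DEFAULT_OVERLAP_FRACTION = 0.5
DEFAULT_MAX_CLASHES = 5


@dataclass
class DockedPose:
    """A ligand conformation placed in a receptor's coordinate frame."""

    ligand: MolecularStructure
    receptor_label: str
    ligand_cluster_label: str = ""
    pose_id: int = 0


@dataclass
class ClashReport:
    pose_id: int
    clash_pairs: list[tuple[int, int, float, float]] = field(default_factory=list)
    # (receptor atom index, ligand atom index, distance A, threshold A)

    @property
    def clash_count(self) -> int:
        return len(self.clash_pairs)


def _heavy_with_radii(s: MolecularStructure, role: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    idx = np.nonzero(s.heavy_mask)[0]
    radii = s.solvation_radius[idx]
    bad = np.nonzero(~np.isfinite(radii) | (radii <= 0))[0]
    if bad.size:
        i = idx[bad[0]]
        raise ParameterError(
            f"missing radius for {role} atom {s.names[i]} "
            f"({s.residue_names[i]} {s.residue_ids[i]})"
        )
    return idx, s.coords[idx], radii


def count_clashes(
    receptor: MolecularStructure,
    pose: DockedPose,
    overlap_fraction: float = DEFAULT_OVERLAP_FRACTION,
) -> ClashReport:
    """Count receptor-ligand heavy-atom clashes for one pose.

    Uses a KD-tree prefilter at the largest possible threshold, then the
    exact per-pair test, so results equal the all-pairs loop.
    """
    ridx, rxyz, rrad = _heavy_with_radii(receptor, "receptor")
    lidx, lxyz, lrad = _heavy_with_radii(pose.ligand, "ligand")
    scale = 1.0 - overlap_fraction
    max_thresh = scale * (rrad.max() + lrad.max())
    pairs = cKDTree(rxyz).query_ball_tree(cKDTree(lxyz), r=max_thresh)
    report = ClashReport(pose_id=pose.pose_id)
    for a, neighbours in enumerate(pairs):
        for b in sorted(neighbours):
            thresh = scale * (rrad[a] + lrad[b])
            d = float(np.linalg.norm(rxyz[a] - lxyz[b]))
            if d < thresh:
                report.clash_pairs.append((int(ridx[a]), int(lidx[b]), d, float(thresh)))
    return report


def filter_poses(
    receptor_frames: dict[str, MolecularStructure],
    poses: list[DockedPose],
    max_clashes: int = DEFAULT_MAX_CLASHES,
    overlap_fraction: float = DEFAULT_OVERLAP_FRACTION,
) -> tuple[list[DockedPose], list[ClashReport]]:
    """Keep poses with at most ``max_clashes`` clashes; order preserved.

    Returns (kept poses, reports of rejected poses).
    """
    kept: list[DockedPose] = []
    rejected: list[ClashReport] = []
    for pose in poses:
        if pose.receptor_label not in receptor_frames:
            raise KeyError(f"unknown receptor label {pose.receptor_label!r}")
        report = count_clashes(receptor_frames[pose.receptor_label], pose, overlap_fraction)
        if report.clash_count <= max_clashes:
            kept.append(pose)
        else:
            rejected.append(report)
    return kept, rejected


def write_clash_reports(reports: list[ClashReport], path: str | Path) -> None:
    lines = ["pose_id\treceptor_atom\tligand_atom\tdistance\tthreshold"]
    for rep in reports:
        for (a, b, d, t) in rep.clash_pairs:
            lines.append(f"{rep.pose_id}\t{a}\t{b}\t{d:.3f}\t{t:.3f}")
    Path(path).write_text("\n".join(lines) + "\n")
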