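"""Torsion-space clustering of ligand conformers and Cartesian clustering
of docked poses into binding modes.

Both clusterers are fixed-radius "leader" algorithms: scan the inputs in
order, assign each item to the first existing cluster whose center lies
within the radius, otherwise seed a new cluster. The torsion clusterer
adds a refinement phase that recomputes centers as per-angle circular
means and reassigns until a fixpoint. The torsion metric is the MAXIMUM
per-angle circular difference (so a 45 deg radius bounds every dihedral);
an RMS-over-angles alternative is available. Mode clustering uses plain
coordinate RMSD over the ligand mainchain (N, CA, C) with no
re-superposition, because docked poses share the receptor frame by
construction.

Leader clustering is order-dependent; identical input order gives
identical output, and callers may pre-sort (e.g. by energy) for
reproducibility across shuffles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .cavities import ClusterAssignment
from .core import AtomSelection, MolecularStructure, dihedral_angle, rmsd

__all__ = [
    "TorsionVector",
    "TorsionClusterSet",
    "ModeClusterSet",
    "circular_difference",
    "extract_torsions",
    "cluster_torsions",
    "cluster_binding_modes",
    "representative_by_energy",
]

DEFAULT_TORSION_RADIUS = 45.0  # deg
DEFAULT_MAX_ERROR = 10.0  # deg, diagnostic center-drift radius
DEFAULT_MODE_RADIUS = 5.0  # A, mainchain RMSD


@dataclass
class TorsionVector:
    frame_label: str
    angles: np.ndarray  # degrees in (-180, 180]

    def __post_init__(self):
        a = np.asarray(self.angles, dtype=float)
        if np.any((a <= -180) | (a > 180)):
            raise ValueError("angles must lie in (-180, 180]")
        self.angles = a


@dataclass
class TorsionClusterSet:
    assignment: ClusterAssignment
    centers: dict[int, np.ndarray]
    max_member_error: dict[int, float]
    center_drift: float  # max center movement in the last refinement pass


@dataclass
class ModeClusterSet:
    assignment: ClusterAssignment
    radius: float
    seeds: dict[int, int] = field(default_factory=dict)  # cluster id -> pose index


# ---------------------------------------------------------------------------

def circular_difference(a: float, b: float) -> float:
    """Smallest absolute angular difference, in [0, 180] degrees."""
    d = np.abs(np.asarray(a, dtype=float) - b) % 360.0
    return float(np.minimum(d, 360.0 - d)) if np.ndim(d) == 0 else np.minimum(d, 360.0 - d)


def _torsion_dist(v: np.ndarray, center: np.ndarray, metric: str) -> float:
    d = np.abs(v - center) % 360.0
    d = np.minimum(d, 360.0 - d)
    if metric == "max":
        return float(d.max())
    if metric == "rms":
        return float(np.sqrt(np.mean(d**2)))
    raise ValueError(f"unknown torsion metric {metric!r}")


def _circular_mean(angles: np.ndarray) -> np.ndarray:
    """Per-angle circular mean, mapped to (-180, 180]."""
    rad = np.radians(angles)
    mean = np.degrees(np.arctan2(np.sin(rad).mean(axis=0), np.cos(rad).mean(axis=0)))
    mean = np.where(mean <= -180.0, mean + 360.0, mean)
    return mean


def extract_torsions(ensemble, dihedral_defs: list[tuple[int, int, int, int]]) -> list[TorsionVector]:
    """One torsion vector per frame; frames with undefined dihedrals are
    skipped with a warning (and recorded in the returned list's gaps)."""
    out: list[TorsionVector] = []
    for i in range(ensemble.n_frames):
        coords = ensemble.frames[i]
        try:
            angles = [dihedral_angle(coords, quad) for quad in dihedral_defs]
        except ValueError as exc:
            warnings.warn(
                f"frame {ensemble.frame_labels[i]!r} skipped: {exc}", stacklevel=2
            )
            continue
        out.append(TorsionVector(frame_label=ensemble.frame_labels[i], angles=np.array(angles)))
    if not out:
        raise ValueError("no frames yielded torsion vectors")
    return out


def cluster_torsions(
    vectors: list[TorsionVector],
    radius: float = DEFAULT_TORSION_RADIUS,
    max_error: float = DEFAULT_MAX_ERROR,
    max_iter: int = 50,
    metric: str = "max",
) -> TorsionClusterSet:
    """Two-phase fixed-radius clustering in circular angle space.

    Phase 1 is a leader pass in input order; phase 2 recomputes centers as
    per-angle circular means and reassigns to the nearest center within
    ``radius`` (else a new cluster is seeded), iterating to a fixpoint or
    ``max_iter``. Cluster ids are assigned by descending population
    (ties: first-seeded). ``max_error`` is a diagnostic: a warning is
    emitted if the final refinement pass moved any center by more.
    """
    if not vectors:
        raise ValueError("no torsion vectors to cluster")
    if radius <= 0:
        raise ValueError("radius must be positive")
    data = np.stack([v.angles for v in vectors])
    n = len(data)

    # Phase 1: leader pass
    centers: list[np.ndarray] = []
    assign = np.empty(n, dtype=int)
    for i in range(n):
        placed = False
        for c, center in enumerate(centers):
            if _torsion_dist(data[i], center, metric) <= radius:
                assign[i] = c
                placed = True
                break
        if not placed:
            centers.append(data[i].copy())
            assign[i] = len(centers) - 1

    # Phase 2: circular-mean refinement to fixpoint
    drift = 0.0
    for _ in range(max_iter):
        new_centers = []
        for c in range(len(centers)):
            members = data[assign == c]
            new_centers.append(_circular_mean(members) if len(members) else centers[c])
        drift = max(
            (
                _torsion_dist(nc, oc, "max")
                for nc, oc in zip(new_centers, centers)
            ),
            default=0.0,
        )
        centers = new_centers
        new_assign = assign.copy()
        for i in range(n):
            dists = [_torsion_dist(data[i], c, metric) for c in centers]
            best = int(np.argmin(dists))
            if dists[best] <= radius:
                new_assign[i] = best
            else:
                centers.append(data[i].copy())
                new_assign[i] = len(centers) - 1
        if np.array_equal(new_assign, assign) and drift < 1e-9:
            break
        assign = new_assign
    if drift > max_error:
        warnings.warn(
            f"center drift {drift:.2f} deg exceeds the max-error radius {max_error} deg",
            stacklevel=2,
        )

    # Drop empty clusters, relabel by descending population (ties: first seed)
    present = [c for c in range(len(centers)) if np.any(assign == c)]
    order = sorted(present, key=lambda c: (-int(np.sum(assign == c)), c))
    relabel = {c: i + 1 for i, c in enumerate(order)}
    ids = np.array([relabel[c] for c in assign])
    labels = [v.frame_label for v in vectors]
    assignment = ClusterAssignment(labels=labels, cluster_ids=ids)
    final_centers = {relabel[c]: centers[c] for c in present}
    max_member_error = {
        cid: max(_torsion_dist(data[i], center, metric) for i in np.nonzero(ids == cid)[0])
        for cid, center in final_centers.items()
    }
    return TorsionClusterSet(
        assignment=assignment,
        centers=final_centers,
        max_member_error=max_member_error,
        center_drift=drift,
    )


def cluster_binding_modes(
    poses: list,
    selection: AtomSelection,
    radius: float = DEFAULT_MODE_RADIUS,
) -> ModeClusterSet:
    """Leader clustering of ligand mainchain coordinates into binding modes.

    ``poses`` is a list of :class:`~posesieve.clashes.DockedPose` (or any
    object with ``.ligand`` and ``.pose_id``); ``selection`` indexes the
    ligand mainchain (N, CA, C) atoms. RMSD is computed on raw coordinates
    without superposition: poses share the receptor frame.
    """
    if not poses:
        raise ValueError("no poses to cluster")
    if len(selection) == 0:
        raise ValueError("empty mainchain selection")
    coords = []
    for p in poses:
        lig = p.ligand if hasattr(p, "ligand") else p
        if selection.indices.max() >= lig.n_atoms:
            raise ValueError("selection out of bounds for pose ligand")
        coords.append(lig.coords[selection.indices])
    seeds: list[int] = []
    assign = np.empty(len(poses), dtype=int)
    for i, xyz in enumerate(coords):
        placed = False
        for c, s in enumerate(seeds):
            if rmsd(xyz, coords[s]) <= radius:
                assign[i] = c
                placed = True
                break
        if not placed:
            seeds.append(i)
            assign[i] = len(seeds) - 1
    labels = [str(getattr(p, "pose_id", i)) for i, p in enumerate(poses)]
    assignment = ClusterAssignment(labels=labels, cluster_ids=assign + 1)
    return ModeClusterSet(
        assignment=assignment,
        radius=radius,
        seeds={c + 1: s for c, s in enumerate(seeds)},
    )


def representative_by_energy(modes: ModeClusterSet, energies: dict) -> dict[int, int]:
    """Per mode, the member pose with minimal energy (ties -> lowest index).

    ``energies`` maps pose label (as stored in the assignment) to kcal/mol.
    Returns cluster id -> member position in the original pose list.
    """
    labels = modes.assignment.labels
    ids = modes.assignment.cluster_ids
    reps: dict[int, int] = {}
    for cid in sorted(set(ids.tolist())):
        members = [i for i in range(len(labels)) if ids[i] == cid]
        for i in members:
            if labels[i] not in energies:
                raise KeyError(f"missing energy for pose {labels[i]!r}")
        reps[cid] = min(members, key=lambda i: (energies[labels[i]], i))
    modes.assignment.representatives = {c: labels[i] for c, i in reps.items()}
    return reps
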