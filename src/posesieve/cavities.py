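"""Binding-cavity shape fingerprints and Jaccard clustering.

A receptor snapshot's binding pocket is described by which points of a
fixed regular grid ("the catalogue") fit inside the cavity: a point is
present when it is farther than an exclusion radius from every receptor
heavy atom and within an inclusion radius of a user-supplied region that
marks the pocket mouth. The resulting binary fingerprints are compared
with the Jaccard binary distance

    J_AB = (C10 + C01) / (C10 + C01 + C11),

where C11 counts grid points present in both fingerprints and C10/C01
count points present only in A or only in B. J = 0 for identical cavity
occupations and 1 for disjoint ones. Snapshots are grouped by average-
linkage hierarchical clustering of the distance matrix with a dendrogram
cut (default 0.3), and each family is represented by its largest-volume
member (most present points).

The default grid spacing of 2.8 A approximates a water diameter, so a set
bit stands for "a water-sized particle fits here"; the default catalogue
box is 50 x 50 x 60 A^3.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial import cKDTree

from .core import MolecularStructure

__all__ = [
    "GridCatalogue",
    "CavityFingerprint",
    "BinaryDistanceMatrix",
    "ClusterAssignment",
    "build_grid_catalogue",
    "compute_cavity_fingerprint",
    "jaccard_distance",
    "fingerprint_distance_matrix",
    "cluster_cavities",
    "select_cavity_representatives",
    "write_fingerprint",
    "read_fingerprint",
    "dendrogram_newick",
]

DEFAULT_SPACING = 2.8  # A, ~ water diameter
DEFAULT_EXCLUSION_RADIUS = 2.4  # A, clearance from receptor heavy atoms
DEFAULT_INCLUSION_RADIUS = 4.0  # A, reach of the pocket-mouth region
DEFAULT_CUT = 0.3  # dendrogram distance cut


@dataclass(frozen=True)
class GridCatalogue:
    """A fixed regular lattice of candidate cavity points.

    Point order is x-fastest: linear index = ix + nx*(iy + ny*iz).
    """

    origin: np.ndarray
    spacing: float
    dims: tuple[int, int, int]

    def __post_init__(self):
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if any(d < 1 for d in self.dims):
            raise ValueError("grid dims must be >= 1")

    @property
    def n_points(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    @property
    def points(self) -> np.ndarray:
        nx, ny, nz = self.dims
        iz, iy, ix = np.meshgrid(
            np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij"
        )
        idx = np.stack([ix.ravel(), iy.ravel(), iz.ravel()], axis=1)
        return self.origin + self.spacing * idx

    @property
    def catalogue_id(self) -> str:
        h = hashlib.sha256()
        h.update(np.round(self.origin, 6).tobytes())
        h.update(np.float64(self.spacing).tobytes())
        h.update(np.asarray(self.dims, dtype=np.int64).tobytes())
        return h.hexdigest()[:16]


@dataclass
class CavityFingerprint:
    """Binary presence vector over a grid catalogue for one snapshot."""

    catalogue_id: str
    bits: np.ndarray
    frame_label: str = ""

    def __post_init__(self):
        self.bits = np.asarray(self.bits, dtype=bool)

    @property
    def volume_count(self) -> int:
        return int(self.bits.sum())


@dataclass
class BinaryDistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(v, v.T) or np.any(np.diag(v) != 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        if np.any((v < 0) | (v > 1)):
            raise ValueError("Jaccard distances must lie in [0, 1]")
        self.values = v

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(path)


@dataclass
class ClusterAssignment:
    """Label -> cluster id, plus one representative label per cluster."""

    labels: list[str]
    cluster_ids: np.ndarray
    representatives: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        self.cluster_ids = np.asarray(self.cluster_ids, dtype=int)
        if len(self.cluster_ids) != len(self.labels):
            raise ValueError("cluster id / label length mismatch")

    @property
    def n_clusters(self) -> int:
        return len(set(self.cluster_ids.tolist()))

    def members(self, cluster_id: int) -> list[str]:
        return [l for l, c in zip(self.labels, self.cluster_ids) if c == cluster_id]


# ---------------------------------------------------------------------------

def build_grid_catalogue(
    origin: np.ndarray, dims: tuple[int, int, int], spacing: float = DEFAULT_SPACING
) -> GridCatalogue:
    """Construct the deterministic lattice catalogue (x-fastest order)."""
    return GridCatalogue(origin=np.asarray(origin, dtype=float), spacing=spacing, dims=dims)


def compute_cavity_fingerprint(
    snapshot: MolecularStructure,
    catalogue: GridCatalogue,
    inclusion_region: np.ndarray,
    exclusion_radius: float = DEFAULT_EXCLUSION_RADIUS,
    inclusion_radius: float = DEFAULT_INCLUSION_RADIUS,
) -> CavityFingerprint:
    """Fingerprint one (pre-superposed) receptor snapshot.

    A grid point is present iff it is farther than ``exclusion_radius``
    from every receptor heavy atom and within ``inclusion_radius`` of at
    least one ``inclusion_region`` coordinate (the pocket-mouth marker).
    Hydrogens are ignored.
    """
    if snapshot.n_atoms == 0:
        raise ValueError("empty snapshot")
    region = np.asarray(inclusion_region, dtype=float).reshape(-1, 3)
    if region.size == 0:
        raise ValueError("inclusion region must be non-empty")
    points = catalogue.points
    heavy = snapshot.coords[snapshot.heavy_mask]
    if heavy.size:
        dmin, _ = cKDTree(heavy).query(points, k=1)
        free = dmin > exclusion_radius
    else:
        free = np.ones(len(points), dtype=bool)
    dreg, _ = cKDTree(region).query(points, k=1)
    bits = free & (dreg <= inclusion_radius)
    if not bits.any():
        warnings.warn(
            f"all-zero fingerprint for {snapshot.frame_label!r}: inclusion region "
            "does not reach the catalogue (misplaced box?)",
            stacklevel=2,
        )
    return CavityFingerprint(
        catalogue_id=catalogue.catalogue_id, bits=bits, frame_label=snapshot.frame_label
    )


def _pair_counts(a: CavityFingerprint, b: CavityFingerprint) -> tuple[int, int, int]:
    c11 = int(np.sum(a.bits & b.bits))
    c10 = int(np.sum(a.bits & ~b.bits))
    c01 = int(np.sum(~a.bits & b.bits))
    return c11, c10, c01


def jaccard_distance(a: CavityFingerprint, b: CavityFingerprint) -> float:
    """Jaccard binary distance between two fingerprints on one catalogue.

    A pair of all-zero fingerprints is defined as distance 0 (with a
    warning): identical empty cavities are maximally similar, but usually
    signal a misplaced catalogue box.
    """
    if a.catalogue_id != b.catalogue_id or len(a.bits) != len(b.bits):
        raise ValueError("fingerprints from different catalogues")
    c11, c10, c01 = _pair_counts(a, b)
    denom = c10 + c01 + c11
    if denom == 0:
        warnings.warn("both fingerprints empty; Jaccard distance defined as 0", stacklevel=2)
        return 0.0
    return (c10 + c01) / denom


def fingerprint_distance_matrix(fps: list[CavityFingerprint]) -> BinaryDistanceMatrix:
    if len(fps) < 2:
        raise ValueError("need at least 2 fingerprints")
    if len({fp.catalogue_id for fp in fps}) != 1:
        raise ValueError("mixed catalogues")
    n = len(fps)
    bits = np.stack([fp.bits for fp in fps]).astype(np.float64)
    c11 = bits @ bits.T
    counts = bits.sum(axis=1)
    union = counts[:, None] + counts[None, :] - c11
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(union > 0, (union - c11) / np.where(union > 0, union, 1), 0.0)
    np.fill_diagonal(d, 0.0)
    labels = [fp.frame_label or f"fp{i}" for i, fp in enumerate(fps)]
    return BinaryDistanceMatrix(labels=labels, values=d)


def _linkage(d: BinaryDistanceMatrix, linkage: str):
    from scipy.spatial.distance import squareform

    if np.any(~np.isfinite(d.values)):
        raise ValueError("NaN/inf in distance matrix")
    condensed = squareform(d.values, checks=False)
    return hierarchy.linkage(condensed, method=linkage)


def cluster_cavities(
    d: BinaryDistanceMatrix, cut: float = DEFAULT_CUT, linkage: str = "average"
) -> ClusterAssignment:
    """Agglomerative clustering of the Jaccard matrix, cut at height ``cut``.

    Cluster ids are renumbered 1..K in order of first appearance along the
    label list (deterministic tie-breaking).
    """
    if not 0 < cut < 1:
        raise ValueError("cut must be in (0, 1)")
    z = _linkage(d, linkage)
    raw = hierarchy.fcluster(z, t=cut, criterion="distance")
    remap: dict[int, int] = {}
    ids = np.empty(len(raw), dtype=int)
    for i, c in enumerate(raw):
        if c not in remap:
            remap[c] = len(remap) + 1
        ids[i] = remap[c]
    return ClusterAssignment(labels=list(d.labels), cluster_ids=ids)


def select_cavity_representatives(
    assignment: ClusterAssignment, fps: list[CavityFingerprint]
) -> dict[int, str]:
    """Per cluster, the largest-volume member (ties -> earliest frame)."""
    by_label = {}
    for i, fp in enumerate(fps):
        label = fp.frame_label or f"fp{i}"
        by_label[label] = (fp.volume_count, i)
    reps: dict[int, str] = {}
    for cid in sorted(set(assignment.cluster_ids.tolist())):
        members = assignment.members(cid)
        best = max(members, key=lambda l: (by_label[l][0], -by_label[l][1]))
        reps[cid] = best
    assignment.representatives = reps
    return reps


# ---------------------------------------------------------------------------
# Persistence: compact text fingerprints and Newick dendrograms
# ---------------------------------------------------------------------------

def write_fingerprint(fp: CavityFingerprint, catalogue: GridCatalogue, path: str | Path) -> None:
    """Write header (origin, spacing, dims, catalogue hash) + RLE bitstring."""
    runs = []
    bits = fp.bits.astype(np.int8)
    if len(bits):
        change = np.nonzero(np.diff(bits))[0] + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [len(bits)]])
        runs = [f"{int(bits[s])}x{e - s}" for s, e in zip(starts, ends)]
    ox, oy, oz = catalogue.origin
    header = [
        f"# cavity fingerprint {fp.frame_label}",
        f"origin {ox:.6f} {oy:.6f} {oz:.6f}",
        f"spacing {catalogue.spacing:.6f}",
        f"dims {catalogue.dims[0]} {catalogue.dims[1]} {catalogue.dims[2]}",
        f"catalogue {catalogue.catalogue_id}",
        f"frame {fp.frame_label}",
        "bits " + ",".join(runs),
    ]
    Path(path).write_text("\n".join(header) + "\n")


def read_fingerprint(path: str | Path) -> tuple[CavityFingerprint, GridCatalogue]:
    fields: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if line.startswith("#") or not line.strip():
            continue
        key, _, rest = line.partition(" ")
        fields[key] = rest.strip()
    origin = np.array([float(x) for x in fields["origin"].split()])
    spacing = float(fields["spacing"])
    dims = tuple(int(x) for x in fields["dims"].split())
    cat = GridCatalogue(origin=origin, spacing=spacing, dims=dims)
    if fields["catalogue"] != cat.catalogue_id:
        raise ValueError("catalogue hash mismatch")
    chunks = []
    if fields.get("bits"):
        for run in fields["bits"].split(","):
            val, count = run.split("x")
            chunks.append(np.full(int(count), bool(int(val))))
    bits = np.concatenate(chunks) if chunks else np.zeros(0, dtype=bool)
    return (
        CavityFingerprint(catalogue_id=cat.catalogue_id, bits=bits, frame_label=fields.get("frame", "")),
        cat,
    )


def dendrogram_newick(d: BinaryDistanceMatrix, linkage: str = "average") -> str:
    """Export the clustering dendrogram as a Newick string for inspection."""
    z = _linkage(d, linkage)
    tree = hierarchy.to_tree(z)

    def rec(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{d.labels[node.id]}:{length:.6f}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6f}"

    return rec(tree, tree.dist) + ";"
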