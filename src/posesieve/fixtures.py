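"""Deterministic synthetic test systems.

Generators for every stage of the framework: a toy membrane receptor
(pseudo-helical bead rods around a central cavity, spanning the membrane
slab), a cyclic six-residue bead ligand with rotatable side chains and
nine defined side-chain dihedrals, planted docked-pose sets (separated
binding modes, optional engineered clash counts), pocket ensembles with
two planted cavity-shape families, and one/two-ion Born systems with
analytic solvation energies.

All generators are pure functions of their arguments (seed included):
identical inputs give bit-identical structures. Bead chemistry is
deliberately simple (one LJ type, small +-0.1 e charges) - enough to
exercise every oracle, with no claim of chemical realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .clashes import DockedPose
from .core import ConformationEnsemble, MolecularStructure, ParameterTable

__all__ = [
    "FixtureSpec",
    "make_toy_receptor",
    "make_cyclic_ligand",
    "cyclic_ligand_dihedrals",
    "rotate_side_chain",
    "make_pose_set",
    "make_pocket_ensemble",
    "make_born_system",
    "cavity_probe_line",
    "fixture_parameter_table",
]

# shared bead parameters: charge by atom name, one LJ/radius type
_BEAD_LJ_EPSILON = 0.12
_BEAD_RMIN_HALF = 1.9
_BEAD_RADIUS = 1.7
_BEAD_CHARGES = {"N": 0.1, "CB": -0.1, "NE": 0.2}


@dataclass
class FixtureSpec:
    """Declarative fixture request; ``build`` dispatches to the maker."""

    seed: int
    kind: str
    parameters: dict = field(default_factory=dict)

    def build(self):
        makers = {
            "toy_receptor": make_toy_receptor,
            "cyclic_ligand": make_cyclic_ligand,
            "pose_set": make_pose_set,
            "pocket_ensemble": make_pocket_ensemble,
            "born_system": make_born_system,
        }
        if self.kind not in makers:
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        return makers[self.kind](seed=self.seed, **self.parameters)


def _finish(struct_args: dict) -> MolecularStructure:
    names = struct_args["names"]
    charges = np.array([_BEAD_CHARGES.get(n, 0.0) for n in names])
    n = len(names)
    return MolecularStructure(
        charges=charges,
        lj_epsilon=np.full(n, _BEAD_LJ_EPSILON),
        lj_rmin_half=np.full(n, _BEAD_RMIN_HALF),
        solvation_radius=np.full(n, _BEAD_RADIUS),
        **struct_args,
    )


def make_toy_receptor(
    seed: int = 0,
    n_rods: int = 7,
    ring_radius: float = 9.0,
    cavity_radius: float = 6.0,
    z_extent: float = 18.0,
    rise: float = 1.5,
    jitter: float = 0.0,
    frame_label: str = "receptor",
) -> MolecularStructure:
    """Pseudo-helical rods on a circle about z, enclosing a central cavity.

    Each rod is a stack of residues (N, CA, C mainchain beads plus an
    inward-pointing CB) spanning |z| <= z_extent; the CB beads sit at
    ``cavity_radius`` + bead radius from the axis, walling off a cavity
    of roughly ``cavity_radius``.
    """
    if cavity_radius >= ring_radius:
        raise ValueError("cavity radius must be smaller than the ring radius")
    rng = np.random.default_rng(seed)
    names, resids, coords = [], [], []
    n_res = int(2 * z_extent / rise) + 1
    resid = 0
    for k in range(n_rods):
        theta = 2 * np.pi * k / n_rods
        u = np.array([np.cos(theta), np.sin(theta), 0.0])
        for j in range(n_res):
            resid += 1
            z = -z_extent + j * rise
            ca = ring_radius * u + np.array([0, 0, z])
            for name, offset in (
                ("N", np.array([0, 0, -0.5])),
                ("CA", np.zeros(3)),
                ("C", np.array([0, 0, 0.5])),
                ("CB", -(ring_radius - cavity_radius - _BEAD_RADIUS) * u),
            ):
                names.append(name)
                resids.append(resid)
                coords.append(ca + offset)
    coords = np.array(coords)
    if jitter > 0:
        coords = coords + rng.normal(0.0, jitter, coords.shape)
    n = len(names)
    return _finish(
        dict(
            names=names,
            elements=["N" if nm.startswith("N") else "C" for nm in names],
            residue_names=["BED"] * n,
            residue_ids=resids,
            chain_ids=["R"] * n,
            coords=coords,
            frame_label=frame_label,
        )
    )


def make_cyclic_ligand(seed: int = 0, frame_label: str = "ligand") -> MolecularStructure:
    """Cyclic six-residue bead peptide with rotatable side chains.

    The mainchain is an 18-bead (N, CA, C per residue) closed ring in the
    xy-plane with ~1.47 A bonds. Residues 1, 4 and 5 carry CB-CG-CD side
    chains, residue 6 carries CB-CG-CD-NE; together they define the nine
    clusterable side-chain dihedrals of :func:`cyclic_ligand_dihedrals`.
    """
    del seed  # geometry is fully deterministic; seed kept for the FixtureSpec contract
    bond = 1.47
    n_ring = 18
    r_ring = bond / (2 * np.sin(np.pi / n_ring))
    names, resids, coords = [], [], []
    side_plan = {1: ["CB", "CG", "CD"], 4: ["CB", "CG", "CD"], 5: ["CB", "CG", "CD"], 6: ["CB", "CG", "CD", "NE"]}
    for res in range(1, 7):
        for a, name in enumerate(("N", "CA", "C")):
            idx = (res - 1) * 3 + a
            phi = 2 * np.pi * idx / n_ring
            names.append(name)
            resids.append(res)
            coords.append([r_ring * np.cos(phi), r_ring * np.sin(phi), 0.0])
        ca = np.array(coords[-2])
        out = ca / np.linalg.norm(ca)
        perp = np.array([0.0, 0.0, 1.0])
        for b, name in enumerate(side_plan.get(res, [])):
            # zig-zag outward chain so successive dihedrals are well defined
            pos = ca + (b + 1) * 1.5 * out + (0.9 if b % 2 else -0.9) * perp * (b > 0)
            names.append(name)
            resids.append(res)
            coords.append(pos)
    n = len(names)
    return _finish(
        dict(
            names=names,
            elements=["N" if nm.startswith("N") else "C" for nm in names],
            residue_names=["LIG"] * n,
            residue_ids=resids,
            chain_ids=["L"] * n,
            coords=np.array(coords),
            frame_label=frame_label,
        )
    )


def cyclic_ligand_dihedrals(ligand: MolecularStructure) -> list[tuple[int, int, int, int]]:
    """The nine side-chain dihedral index quadruples of the cyclic ligand."""
    def find(res: int, name: str) -> int:
        hits = np.nonzero((ligand.residue_ids == res) & (ligand.names == name))[0]
        if hits.size != 1:
            raise ValueError(f"atom {name} of residue {res} not found")
        return int(hits[0])

    quads = []
    for res in (1, 4, 5, 6):
        quads.append((find(res, "N"), find(res, "CA"), find(res, "CB"), find(res, "CG")))
        quads.append((find(res, "CA"), find(res, "CB"), find(res, "CG"), find(res, "CD")))
    quads.append((find(6, "CB"), find(6, "CG"), find(6, "CD"), find(6, "NE")))
    return quads


def rotate_side_chain(
    ligand: MolecularStructure, residue: int, angle_deg: float
) -> MolecularStructure:
    """Rotate a residue's side chain (beyond CB) about its CA-CB axis."""
    res_mask = ligand.residue_ids == residue
    ca = ligand.coords[np.nonzero(res_mask & (ligand.names == "CA"))[0][0]]
    cb = ligand.coords[np.nonzero(res_mask & (ligand.names == "CB"))[0][0]]
    axis = cb - ca
    axis = axis / np.linalg.norm(axis)
    moving = np.nonzero(res_mask & np.isin(ligand.names.astype(str), ["CG", "CD", "NE"]))[0]
    from scipy.spatial.transform import Rotation

    rot = Rotation.from_rotvec(np.radians(angle_deg) * axis)
    coords = ligand.coords.copy()
    coords[moving] = rot.apply(coords[moving] - cb) + cb
    return ligand.with_coords(coords)


def make_pose_set(
    seed: int = 0,
    receptor: MolecularStructure | None = None,
    ligand: MolecularStructure | None = None,
    n_modes: int = 3,
    poses_per_mode: int = 5,
    mode_separation: float = 12.0,
    jitter: float = 0.5,
    clash_counts: list[int] | None = None,
    receptor_label: str = "receptor",
) -> list[DockedPose]:
    """Planted pose set: ``n_modes`` translation modes plus clash poses.

    Modes are rigid translations of the ligand along orthogonal-ish
    directions, mutually separated by ``mode_separation`` (> 2x the 5 A
    mode radius by default) in mainchain RMSD; per-pose positional jitter
    is isotropic with RMS ``jitter``. Each entry of ``clash_counts``
    appends one pose engineered to clash with exactly that many receptor
    atoms (one ligand atom per clash, mutually distant receptor targets).
    """
    rng = np.random.default_rng(seed)
    receptor = receptor if receptor is not None else make_toy_receptor(seed=seed)
    ligand = ligand if ligand is not None else make_cyclic_ligand(seed=seed)
    directions = np.array(
        [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 0], [1, 0, 1], [0, 1, 1]],
        dtype=float,
    )
    directions[1:] /= np.linalg.norm(directions[1:], axis=1, keepdims=True)
    if n_modes > len(directions):
        raise ValueError("too many modes requested")
    poses: list[DockedPose] = []
    pid = 0
    for mode in range(n_modes):
        base_shift = directions[mode] * mode_separation + np.array([0.0, 0.0, 25.0])
        for _ in range(poses_per_mode):
            shift = base_shift + rng.normal(0.0, jitter / np.sqrt(3), 3)
            poses.append(
                DockedPose(
                    ligand=ligand.with_coords(ligand.coords + shift, frame_label=f"pose{pid}"),
                    receptor_label=receptor_label,
                    ligand_cluster_label=f"mode{mode}",
                    pose_id=pid,
                )
            )
            pid += 1
    for c in clash_counts or []:
        poses.append(
            _engineered_clash_pose(receptor, ligand, c, pid, receptor_label)
        )
        pid += 1
    return poses


def _engineered_clash_pose(
    receptor: MolecularStructure,
    ligand: MolecularStructure,
    n_clashes: int,
    pose_id: int,
    receptor_label: str,
) -> DockedPose:
    """A pose whose first ``n_clashes`` ligand atoms each overlap one
    mutually distant receptor atom; all other atoms are far away."""
    if n_clashes > ligand.n_atoms:
        raise ValueError("more clashes requested than ligand atoms")
    # Targets are CA beads spaced far apart; the planted atom sits in the
    # target's z-plane, radially outward, just inside the clash threshold
    # of the CA but outside the thresholds of the z-offset N/C neighbours.
    cas = np.nonzero((receptor.names == "CA") & receptor.heavy_mask)[0]
    targets: list[int] = []
    for i in cas:
        if all(np.linalg.norm(receptor.coords[i] - receptor.coords[t]) > 9.0 for t in targets):
            targets.append(int(i))
        if len(targets) == n_clashes:
            break
    if len(targets) < n_clashes:
        raise ValueError("receptor too small for the requested clash count")
    coords = ligand.coords + np.array([0.0, 0.0, 120.0])  # parked far away
    for a, t in enumerate(targets):
        c = receptor.coords[t]
        radial = np.array([c[0], c[1], 0.0])
        direction = radial / np.linalg.norm(radial)
        d = 0.485 * (receptor.solvation_radius[t] + ligand.solvation_radius[a])
        coords[a] = c + direction * d
    return DockedPose(
        ligand=ligand.with_coords(coords, frame_label=f"clash{n_clashes}"),
        receptor_label=receptor_label,
        ligand_cluster_label=f"clash{n_clashes}",
        pose_id=pose_id,
    )


def make_pocket_ensemble(
    seed: int = 0,
    n_frames_per_family: int = 5,
    jitter: float = 0.05,
    plug_z: float = 6.0,
    receptor_kwargs: dict | None = None,
) -> ConformationEnsemble:
    """Receptor snapshots with two planted cavity-shape families.

    The topology is a toy receptor plus a line of "plug" beads. In family
    A frames the plug is retracted into the wall (open cavity); in family
    B it sits on the pore axis, occluding the upper cavity. Within-family
    coordinate jitter is small, so Jaccard distances are near 0 within a
    family and large between families.
    """
    rng = np.random.default_rng(seed)
    base = make_toy_receptor(seed=seed, **(receptor_kwargs or {}))
    # plug: a 5-column brush of beads occluding the upper half of the pore
    # when closed, parked well outside the wall when open
    xy_offsets = np.array([[0.0, 0.0], [2.2, 0.0], [-2.2, 0.0], [0.0, 2.2], [0.0, -2.2]])
    z_levels = np.arange(plug_z - 16.0, plug_z + 0.1, 2.0)
    closed_pos = np.array([[x, y, z] for z in z_levels for x, y in xy_offsets])
    n_plug = len(closed_pos)
    open_pos = closed_pos + np.array([16.0, 0.0, 0.0])
    plug_names = ["CB"] * n_plug
    plug_resids = [int(base.residue_ids.max()) + 1 + i for i in range(n_plug)]
    topo = _finish(
        dict(
            names=list(base.names) + plug_names,
            elements=list(base.elements) + ["C"] * n_plug,
            residue_names=list(base.residue_names) + ["PLG"] * n_plug,
            residue_ids=list(base.residue_ids) + plug_resids,
            chain_ids=list(base.chain_ids) + ["P"] * n_plug,
            coords=np.vstack([base.coords, open_pos]),
            frame_label="pocket",
        )
    )
    frames = []
    labels = []
    for fam, plug in (("A", open_pos), ("B", closed_pos)):
        for i in range(n_frames_per_family):
            xyz = np.vstack([base.coords, plug])
            xyz = xyz + rng.normal(0.0, jitter, xyz.shape)
            frames.append(xyz)
            labels.append(f"{fam}{i}")
    return ConformationEnsemble(topo, np.array(frames), labels)


def cavity_probe_line(z_lo: float = -12.0, z_hi: float = 12.0, step: float = 2.0) -> np.ndarray:
    """Points along the pore axis, used as the fingerprint inclusion region."""
    zs = np.arange(z_lo, z_hi + 1e-9, step)
    return np.stack([np.zeros_like(zs), np.zeros_like(zs), zs], axis=1)


def make_born_system(
    seed: int = 0,
    charges: tuple[float, ...] = (1.0,),
    radius: float = 2.0,
    separation: float = 0.0,
    z_center: float = 0.0,
) -> MolecularStructure:
    """One or more ions on the z-axis with analytic Born energetics.

    Ions are spaced ``separation`` apart along x at height ``z_center``.
    A single ion's aqueous GB/PB solvation has the closed form
    -(k/2)(1/eps_in - 1/eps_out) q^2 / radius.
    """
    del seed
    n = len(charges)
    coords = np.array([[i * separation, 0.0, z_center] for i in range(n)])
    return MolecularStructure(
        names=[f"I{i+1}" for i in range(n)],
        elements=["C"] * n,
        residue_names=["ION"] * n,
        residue_ids=list(range(1, n + 1)),
        chain_ids=["I"] * n,
        coords=coords,
        charges=np.array(charges, dtype=float),
        lj_epsilon=np.full(n, _BEAD_LJ_EPSILON),
        lj_rmin_half=np.full(n, radius),
        solvation_radius=np.full(n, radius),
        frame_label="born",
    )


def fixture_parameter_table(*structures: MolecularStructure) -> ParameterTable:
    """Parameter table covering the given fixture structures.

    Fixture bead parameters are constant per (residue name, atom name),
    so the table reproduces the arrays exactly on re-application.
    """
    table = ParameterTable()
    for s in structures:
        for i in range(s.n_atoms):
            key = (str(s.residue_names[i]), str(s.names[i]))
            row = (
                float(s.charges[i]),
                float(s.lj_epsilon[i]),
                float(s.lj_rmin_half[i]),
                float(s.solvation_radius[i]),
            )
            if key in table and table[key] != row:
                raise ValueError(f"inconsistent parameters for {key}")
            table[key] = row
    return table


def cyclic_ligand_dihedral_config() -> list:
    """The nine dihedrals as (resid, atom-name) quadruples for run configs."""
    quads = []
    for res in (1, 4, 5, 6):
        quads.append([[res, "N"], [res, "CA"], [res, "CB"], [res, "CG"]])
        quads.append([[res, "CA"], [res, "CB"], [res, "CG"], [res, "CD"]])
    quads.append([[6, "CB"], [6, "CG"], [6, "CD"], [6, "NE"]])
    return quads


def write_fixture_bundle(outdir, seed: int = 0, small: bool = True) -> dict:
    """Write a complete end-to-end input bundle (PDB files + parameters).

    Contents: a two-family receptor pocket ensemble, a two-family ligand
    conformer ensemble, a multi-model pose file (two planted binding modes
    plus one heavy clasher) and the shared parameter table. Returns the
    paths keyed as the run-config expects them.
    """
    from pathlib import Path

    from .core import write_parameter_table, write_structure

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    receptor_kwargs = dict(n_rods=5, z_extent=9.0, rise=3.0) if small else {}
    rec_ens = make_pocket_ensemble(
        seed=seed, n_frames_per_family=2, jitter=0.02,
        receptor_kwargs=receptor_kwargs,
    )
    ligand = make_cyclic_ligand(seed=seed)
    rotated = rotate_side_chain(ligand, 1, 120.0)
    lig_ens = ConformationEnsemble(
        ligand,
        np.array([ligand.coords, ligand.coords, rotated.coords, rotated.coords]),
        ["l0", "l1", "l2", "l3"],
    )
    receptor = make_toy_receptor(seed=seed, **receptor_kwargs)
    poses = make_pose_set(
        seed=seed, receptor=receptor, ligand=ligand,
        n_modes=2, poses_per_mode=2, clash_counts=[9],
    )
    pose_ens = ConformationEnsemble(
        ligand,
        np.array([p.ligand.coords for p in poses]),
        [f"pose{p.pose_id}" for p in poses],
    )
    paths = {
        "receptor_ensemble": str(out / "receptor_ensemble.pdb"),
        "ligand_ensemble": str(out / "ligand_ensemble.pdb"),
        "poses": str(out / "poses.pdb"),
        "parameter_table": str(out / "parameters.txt"),
    }
    write_structure(rec_ens, paths["receptor_ensemble"])
    write_structure(lig_ens, paths["ligand_ensemble"])
    write_structure(pose_ens, paths["poses"])
    table = fixture_parameter_table(rec_ens.topology, ligand)
    write_parameter_table(table, paths["parameter_table"])
    return paths
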