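"""Binding free energies, the pose sieve, residue-pair decomposition and
contact / hydrogen-bond probability maps.

Binding free energy (rigid, single-geometry end-point approximation):

    dG = G_PL - G_P - G_L
       = E_inter^Coul(eps=1) + E_inter^vdW
         + [G_solv(PL) - G_solv(P) - G_solv(L)]
         + gamma * [SASA(PL) - SASA(P) - SASA(L)]

Complex and receptor solvation use the membrane environment; the free
ligand is solvated in water. Receptor and ligand conformations are taken
identical in bound and free states, so bonded and intramolecular
nonbonded terms cancel; configurational entropy is omitted.

The sieve orders the post-docking stages: clash filter ->
uniform-dielectric steepest-descent minimization -> MM-GBSA scoring ->
energy-window filter (default 27 kcal/mol above the minimum) -> MM-PBSA
rescoring -> mainchain mode clustering (5 A radius) -> lowest-PBSA
representative per mode.

Residue-pair interaction free energies: for receptor residue R and
ligand residue R',

    dG_inte(R, R') = [ sum_{i in R, j in R'} (E^Coul_ij + G^GB_ij) ]   (polar)
                   + [ sum_{i in R, j in R'} E^vdW_ij + sigma * sum dS_i ]  (nonpolar)

The GB cross term uses Born radii computed once from the full complex and
held fixed, which makes the decomposition exactly additive: the polar
terms summed over all pairs recover the complex's total intermolecular
polar cross energy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .clashes import DockedPose, filter_poses
from .conformers import cluster_binding_modes, representative_by_energy
from .core import (
    AtomSelection,
    ConformationEnsemble,
    MolecularStructure,
    geometric_center,
)
from .solvent import (
    AQUEOUS,
    COULOMB_K,
    EnergyBreakdown,
    GridSpec,
    MembraneModel,
    accessible_surface_area,
    coulomb_energy,
    effective_born_radii,
    gb_solvation_energy,
    lennard_jones_energy,
    nonpolar_surface_energy,
    pb_solvation_energy,
    steepest_descent_minimize,
)

__all__ = [
    "BindingScore",
    "PairInteractionTable",
    "ContactProbabilityMaps",
    "HBondProbabilityMap",
    "SievedSet",
    "mmgbsa_binding_energy",
    "mmpbsa_binding_energy",
    "energy_window_filter",
    "sieve_poses",
    "trajectory_average_binding",
    "pairwise_interaction_decomposition",
    "contact_probability_maps",
    "hbond_probability_map",
]

DEFAULT_WINDOW = 27.0  # kcal/mol above the binding free-energy minimum
DEFAULT_CONTACT_THRESHOLD = 6.5  # A, moiety geometric centers
DEFAULT_HBOND_DMAX = 3.5  # A, donor-acceptor heavy-atom distance
DEFAULT_HBOND_ANGLE_MIN = 90.0  # deg, D-H...A


@dataclass
class BindingScore:
    pose_id: int
    dg_gbsa: float
    dg_pbsa: float | None = None
    components: dict[str, EnergyBreakdown] = field(default_factory=dict)


@dataclass
class PairInteractionTable:
    """Rows of per residue-pair polar/nonpolar interaction free energies."""

    rows: pd.DataFrame  # receptor_residue, ligand_residue, polar, nonpolar, total

    def sorted_by_magnitude(self) -> pd.DataFrame:
        return self.rows.reindex(
            self.rows["total"].abs().sort_values(ascending=False).index
        ).reset_index(drop=True)

    def significant(self, min_energy: float = 1.8) -> pd.DataFrame:
        df = self.sorted_by_magnitude()
        return df[df["total"].abs() >= min_energy].reset_index(drop=True)

    def to_tsv(self, path: str | Path) -> None:
        self.sorted_by_magnitude().to_csv(path, sep="\t", index=False)


@dataclass
class ContactProbabilityMaps:
    """Occupancy (%) matrices for the four moiety pairings."""

    receptor_residues: list[tuple[str, int]]
    ligand_residues: list[tuple[str, int]]
    maps: dict[str, np.ndarray]  # keys: sc-sc, mc-mc, sc-mc, mc-sc
    undefined: dict[str, np.ndarray] | None = None  # empty-moiety flags

    def to_frames(self) -> dict[str, pd.DataFrame]:
        ridx = [f"{c}:{r}" for c, r in self.receptor_residues]
        lidx = [f"{c}:{r}" for c, r in self.ligand_residues]
        return {k: pd.DataFrame(v, index=ridx, columns=lidx) for k, v in self.maps.items()}

    def plot(self, path: str | Path) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(2, 2, figsize=(10, 8))
        for ax, (key, mat) in zip(axes.ravel(), self.maps.items()):
            im = ax.imshow(mat, vmin=0, vmax=100, cmap="viridis")
            ax.set_title(key)
            fig.colorbar(im, ax=ax, label="occupancy %")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


@dataclass
class HBondProbabilityMap:
    """(donor atom, acceptor atom) -> occupancy %, with fallback flags."""

    occupancy: dict[tuple[str, str], float]
    angle_waived: set[tuple[str, str]] = field(default_factory=set)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "donor": d,
                "acceptor": a,
                "occupancy_percent": round(v, 1),
                "angle_waived": (d, a) in self.angle_waived,
            }
            for (d, a), v in sorted(self.occupancy.items())
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# End-point binding free energies
# ---------------------------------------------------------------------------

def _check_partition(complex_: MolecularStructure, rsel: AtomSelection, lsel: AtomSelection):
    r, l = set(rsel.indices.tolist()), set(lsel.indices.tolist())
    if r & l:
        raise ValueError("receptor/ligand selections overlap")
    if r | l != set(range(complex_.n_atoms)):
        raise ValueError("selections must partition the complex")


def mmgbsa_binding_energy(
    complex_: MolecularStructure,
    receptor_sel: AtomSelection,
    ligand_sel: AtomSelection,
    m: MembraneModel = MembraneModel(),
    pose_id: int = 0,
    ligand_membrane_context: bool = False,
    sasa_points: int = 960,
) -> BindingScore:
    """Rigid MM-GBSA binding free energy of a complex geometry.

    Complex and receptor are solvated in the membrane environment, the
    free ligand in water (``ligand_membrane_context=True`` keeps the
    ligand in the membrane context, for closed-system checks).
    """
    _check_partition(complex_, receptor_sel, ligand_sel)
    ri, li = receptor_sel.indices, ligand_sel.indices
    receptor = complex_.subset(ri)
    ligand = complex_.subset(li)

    e_coul = coulomb_energy(complex_, pairs=(ri, li), dielectric=m.eps_mm_interior)
    e_vdw = lennard_jones_energy(complex_, pairs=(ri, li))

    gb_pl = gb_solvation_energy(complex_, effective_born_radii(complex_, m), m)
    gb_p = gb_solvation_energy(receptor, effective_born_radii(receptor, m), m)
    lig_ctx = m if ligand_membrane_context else AQUEOUS
    gb_l = gb_solvation_energy(ligand, effective_born_radii(ligand, lig_ctx), lig_ctx)

    sasa_pl = accessible_surface_area(complex_, n_points=sasa_points).sum()
    sasa_p = accessible_surface_area(receptor, n_points=sasa_points).sum()
    sasa_l = accessible_surface_area(ligand, n_points=sasa_points).sum()
    e_np = m.gamma * (sasa_pl - sasa_p - sasa_l)

    dg = e_coul + e_vdw + (gb_pl - gb_p - gb_l) + e_np
    components = {
        "delta": EnergyBreakdown(
            coulomb=e_coul, vdw=e_vdw, gb_solvation=gb_pl - gb_p - gb_l, nonpolar_surface=e_np
        ),
        "PL": EnergyBreakdown(gb_solvation=gb_pl, nonpolar_surface=m.gamma * sasa_pl),
        "P": EnergyBreakdown(gb_solvation=gb_p, nonpolar_surface=m.gamma * sasa_p),
        "L": EnergyBreakdown(gb_solvation=gb_l, nonpolar_surface=m.gamma * sasa_l),
    }
    return BindingScore(pose_id=pose_id, dg_gbsa=float(dg), components=components)


def mmpbsa_binding_energy(
    complex_: MolecularStructure,
    receptor_sel: AtomSelection,
    ligand_sel: AtomSelection,
    m: MembraneModel = MembraneModel(),
    g: GridSpec = GridSpec(),
    pose_id: int = 0,
    sasa_points: int = 960,
    tol: float = 1e-6,
) -> BindingScore:
    """Rigid MM-PBSA binding free energy.

    All three contexts share the same grid geometry; the receptor context
    simply drops the ligand atoms (charges and dielectric spheres) and
    vice versa, so spread-charge self energies cancel in the difference.
    """
    _check_partition(complex_, receptor_sel, ligand_sel)
    ri, li = receptor_sel.indices, ligand_sel.indices
    receptor = complex_.subset(ri)
    ligand = complex_.subset(li)

    e_coul = coulomb_energy(complex_, pairs=(ri, li), dielectric=m.eps_mm_interior)
    e_vdw = lennard_jones_energy(complex_, pairs=(ri, li))

    pb_pl = pb_solvation_energy(complex_, g, m, mode="membrane", tol=tol)
    pb_p = pb_solvation_energy(receptor, g, m, mode="membrane", tol=tol)
    pb_l = pb_solvation_energy(ligand, g, m, mode="aqueous", tol=tol)

    sasa_pl = accessible_surface_area(complex_, n_points=sasa_points).sum()
    sasa_p = accessible_surface_area(receptor, n_points=sasa_points).sum()
    sasa_l = accessible_surface_area(ligand, n_points=sasa_points).sum()
    e_np = m.gamma * (sasa_pl - sasa_p - sasa_l)

    dg = e_coul + e_vdw + (pb_pl - pb_p - pb_l) + e_np
    score = BindingScore(pose_id=pose_id, dg_gbsa=float("nan"), dg_pbsa=float(dg))
    score.components["delta"] = EnergyBreakdown(
        coulomb=e_coul, vdw=e_vdw, pb_solvation=pb_pl - pb_p - pb_l, nonpolar_surface=e_np
    )
    return score


def energy_window_filter(
    scores: list[BindingScore], window: float = DEFAULT_WINDOW, field: str = "gbsa"
) -> list[int]:
    """Pose ids whose dG lies within ``window`` of the minimum (<=)."""
    if not scores:
        raise ValueError("no scores to filter")
    values = {
        s.pose_id: (s.dg_gbsa if field == "gbsa" else s.dg_pbsa) for s in scores
    }
    if any(v is None or not np.isfinite(v) for v in values.values()):
        raise ValueError(f"field {field!r} not populated for all poses")
    cutoff = min(values.values()) + window
    return [s.pose_id for s in scores if values[s.pose_id] <= cutoff]


# ---------------------------------------------------------------------------
# The sieve
# ---------------------------------------------------------------------------

@dataclass
class SievedSet:
    kept: list[DockedPose]
    scores: dict[int, BindingScore]
    mode_assignment: "object"
    representatives: dict[int, int]  # mode id -> pose id
    ledger: pd.DataFrame
    stage_counts: dict[str, int]


def _assemble_complex(receptor: MolecularStructure, ligand: MolecularStructure):
    """Concatenate receptor + ligand into one structure; returns the
    complex plus receptor/ligand selections."""
    n_r, n_l = receptor.n_atoms, ligand.n_atoms
    complex_ = MolecularStructure(
        names=np.concatenate([receptor.names, ligand.names]),
        elements=np.concatenate([receptor.elements, ligand.elements]),
        residue_names=np.concatenate([receptor.residue_names, ligand.residue_names]),
        residue_ids=np.concatenate([receptor.residue_ids, ligand.residue_ids]),
        chain_ids=np.concatenate([receptor.chain_ids, ligand.chain_ids]),
        coords=np.vstack([receptor.coords, ligand.coords]),
        charges=np.concatenate([receptor.charges, ligand.charges]),
        lj_epsilon=np.concatenate([receptor.lj_epsilon, ligand.lj_epsilon]),
        lj_rmin_half=np.concatenate([receptor.lj_rmin_half, ligand.lj_rmin_half]),
        solvation_radius=np.concatenate([receptor.solvation_radius, ligand.solvation_radius]),
        mainchain_names=receptor.mainchain_names | ligand.mainchain_names,
    )
    rsel = AtomSelection("receptor", np.arange(n_r))
    lsel = AtomSelection("ligand", np.arange(n_r, n_r + n_l))
    return complex_, rsel, lsel


def sieve_poses(
    receptor_frames: dict[str, MolecularStructure],
    poses: list[DockedPose],
    m: MembraneModel = MembraneModel(),
    g: GridSpec | None = None,
    max_clashes: int = 5,
    overlap_fraction: float = 0.5,
    minimize_steps: int = 100,
    minimize_dielectric: float = 4.0,
    window: float = DEFAULT_WINDOW,
    mode_radius: float = 5.0,
    mainchain_selection: str = "name N,CA,C",
    sasa_points: int = 960,
    pb_tol: float = 1e-4,
    run_pbsa: bool = True,
) -> SievedSet:
    """Run the full post-docking sieve on a pose set.

    Stages: (1) clash filter, (2) steepest-descent minimization of the
    ligand in the rigid receptor field (eps = ``minimize_dielectric``),
    (3) MM-GBSA scoring, (4) energy-window filter, (5) MM-PBSA rescoring,
    (6) mainchain binding-mode clustering, (7) lowest-PBSA representative
    per mode. Stage in/out counts are recorded in the ledger.
    """
    counts: dict[str, int] = {"input": len(poses)}
    rows: list[dict] = []
    for p in poses:
        rows.append({"pose_id": p.pose_id, "receptor": p.receptor_label, "stage_reached": "input"})
    ledger = pd.DataFrame(rows).set_index("pose_id")

    # 1. clash filter
    kept, rejected = filter_poses(receptor_frames, poses, max_clashes, overlap_fraction)
    for rep in rejected:
        ledger.loc[rep.pose_id, "stage_reached"] = "clash_rejected"
        ledger.loc[rep.pose_id, "clash_count"] = rep.clash_count
    counts["after_clash_filter"] = len(kept)
    if not kept:
        raise RuntimeError("sieve aborted at stage clash_filter: no poses survive")

    # 2. minimization (ligand mobile, receptor fixed) + 3. GBSA
    scores: dict[int, BindingScore] = {}
    minimized: dict[int, DockedPose] = {}
    for pose in kept:
        receptor = receptor_frames[pose.receptor_label]
        complex_, rsel, lsel = _assemble_complex(receptor, pose.ligand)
        relaxed = steepest_descent_minimize(
            complex_, n_steps=minimize_steps, dielectric=minimize_dielectric, fixed=rsel.indices
        )
        new_lig = pose.ligand.with_coords(relaxed.coords[lsel.indices])
        minimized[pose.pose_id] = DockedPose(
            ligand=new_lig,
            receptor_label=pose.receptor_label,
            ligand_cluster_label=pose.ligand_cluster_label,
            pose_id=pose.pose_id,
        )
        score = mmgbsa_binding_energy(
            relaxed, rsel, lsel, m, pose_id=pose.pose_id, sasa_points=sasa_points
        )
        scores[pose.pose_id] = score
        ledger.loc[pose.pose_id, "stage_reached"] = "gbsa_scored"
        ledger.loc[pose.pose_id, "dg_gbsa"] = score.dg_gbsa
    counts["after_minimization"] = len(minimized)

    # 4. energy window
    surviving_ids = set(
        energy_window_filter(list(scores.values()), window=window, field="gbsa")
    )
    survivors = [minimized[p.pose_id] for p in kept if p.pose_id in surviving_ids]
    for p in kept:
        if p.pose_id not in surviving_ids:
            ledger.loc[p.pose_id, "stage_reached"] = "window_rejected"
    counts["after_window_filter"] = len(survivors)
    if not survivors:
        raise RuntimeError("sieve aborted at stage window_filter: no poses survive")

    # 5. PBSA rescore
    for pose in survivors:
        receptor = receptor_frames[pose.receptor_label]
        complex_, rsel, lsel = _assemble_complex(receptor, pose.ligand)
        if run_pbsa and g is not None:
            pb = mmpbsa_binding_energy(
                complex_, rsel, lsel, m, g, pose_id=pose.pose_id,
                sasa_points=sasa_points, tol=pb_tol,
            )
            scores[pose.pose_id].dg_pbsa = pb.dg_pbsa
            scores[pose.pose_id].components["delta_pbsa"] = pb.components["delta"]
        else:
            # PB grid not configured: carry the GBSA score forward
            scores[pose.pose_id].dg_pbsa = scores[pose.pose_id].dg_gbsa
        ledger.loc[pose.pose_id, "stage_reached"] = "pbsa_scored"
        ledger.loc[pose.pose_id, "dg_pbsa"] = scores[pose.pose_id].dg_pbsa
    counts["after_pbsa"] = len(survivors)

    # 6. mode clustering on ligand mainchain N/CA/C
    sel = survivors[0].ligand.select(mainchain_selection)
    modes = cluster_binding_modes(survivors, sel, radius=mode_radius)
    for pose, cid in zip(survivors, modes.assignment.cluster_ids):
        ledger.loc[pose.pose_id, "mode"] = int(cid)
    counts["modes"] = modes.assignment.n_clusters

    # 7. representatives by PBSA energy
    energies = {str(p.pose_id): scores[p.pose_id].dg_pbsa for p in survivors}
    rep_positions = representative_by_energy(modes, energies)
    representatives = {cid: survivors[pos].pose_id for cid, pos in rep_positions.items()}
    for cid, pid in representatives.items():
        ledger.loc[pid, "is_representative"] = True
    counts["representatives"] = len(representatives)

    return SievedSet(
        kept=survivors,
        scores=scores,
        mode_assignment=modes,
        representatives=representatives,
        ledger=ledger.reset_index(),
        stage_counts=counts,
    )


def trajectory_average_binding(
    ensemble: ConformationEnsemble,
    receptor_sel: AtomSelection,
    ligand_sel: AtomSelection,
    m: MembraneModel = MembraneModel(),
    g: GridSpec | None = None,
    stride: int = 1,
    method: str = "gbsa",
    sasa_points: int = 960,
    pb_tol: float = 1e-4,
) -> tuple[float, float, int]:
    """Mean and sd of per-frame binding free energies over a trajectory.

    Frames failing energetics are skipped with a warning; returns
    (mean, sd, n_failed).
    """
    frames = list(range(0, ensemble.n_frames, stride))
    if len(frames) < 2:
        raise ValueError("need at least 2 frames after stride")
    values = []
    failed = 0
    for i in frames:
        frame = ensemble.structure(i)
        try:
            if method == "pbsa":
                score = mmpbsa_binding_energy(
                    frame, receptor_sel, ligand_sel, m, g or GridSpec(),
                    sasa_points=sasa_points, tol=pb_tol,
                )
                values.append(score.dg_pbsa)
            else:
                score = mmgbsa_binding_energy(
                    frame, receptor_sel, ligand_sel, m, sasa_points=sasa_points
                )
                values.append(score.dg_gbsa)
        except Exception as exc:  # recorded, frame skipped
            failed += 1
            warnings.warn(f"frame {i} failed: {exc}", stacklevel=2)
    if not values:
        raise RuntimeError("all frames failed")
    return float(np.mean(values)), float(np.std(values)), failed


# ---------------------------------------------------------------------------
# Residue-pair decomposition
# ---------------------------------------------------------------------------

def _gb_cross_term(
    s: MolecularStructure, radii: np.ndarray, ia: np.ndarray, ib: np.ndarray,
    eps_in: float, eps_out: float,
) -> float:
    """GB cross energy between atom groups A and B at fixed Born radii.

    Equals gb(A u B) - gb(A) - gb(B) under the charge-mask convention."""
    qa, qb = s.charges[ia], s.charges[ib]
    dx = s.coords[ia][:, None, :] - s.coords[ib][None, :, :]
    r2 = np.sum(dx * dx, axis=-1)
    aa = radii[ia][:, None] * radii[ib][None, :]
    f = np.sqrt(r2 + aa * np.exp(-r2 / (4.0 * aa)))
    pref = -0.5 * COULOMB_K * (1.0 / eps_in - 1.0 / eps_out)
    return float(2.0 * pref * np.sum(qa[:, None] * qb[None, :] / f))


def pairwise_interaction_decomposition(
    complex_: MolecularStructure,
    receptor_sel: AtomSelection,
    ligand_sel: AtomSelection,
    m: MembraneModel = MembraneModel(),
    pairs: list[tuple[tuple[str, int], tuple[str, int]]] | None = None,
    surface_attribution: str = "max-vdw",
    sasa_points: int = 960,
) -> PairInteractionTable:
    """Per residue-pair polar and nonpolar interaction free energies.

    Born radii are computed once from the full complex (membrane context)
    and held fixed for every charge-masked GB evaluation. The sigma*dSASA
    surface term of each residue (complex minus unbound context) is
    attributed to the residue's single highest-|vdW| partner pair
    (``"max-vdw"``, default) or split evenly over its partners
    (``"even-split"``); either way the total surface energy is counted
    once across the table.
    """
    _check_partition(complex_, receptor_sel, ligand_sel)
    radii = effective_born_radii(complex_, m).radii
    eps_in, eps_out = m.eps_mm_interior, m.eps_water

    res_of = {}
    for key, sl in complex_.residue_index.items():
        res_of[key] = np.arange(sl.start, sl.stop)
    rset, lset = set(receptor_sel.indices.tolist()), set(ligand_sel.indices.tolist())
    r_residues = [k for k, idx in res_of.items() if set(idx.tolist()) <= rset]
    l_residues = [k for k, idx in res_of.items() if set(idx.tolist()) <= lset]
    for k, idx in res_of.items():
        ids = set(idx.tolist())
        if not (ids <= rset or ids <= lset):
            raise ValueError(f"residue {k} straddles the receptor/ligand split")

    if pairs is None:
        pairs = [(r, l) for r in r_residues for l in l_residues]
    for r, l in pairs:
        if len(res_of.get(r, ())) == 0 or len(res_of.get(l, ())) == 0:
            raise ValueError(f"residue pair ({r}, {l}) has no atoms")

    # SASA difference per residue (complex vs unbound context)
    sasa_cplx = accessible_surface_area(complex_, n_points=sasa_points)
    receptor = complex_.subset(receptor_sel.indices)
    ligand = complex_.subset(ligand_sel.indices)
    sasa_r = accessible_surface_area(receptor, n_points=sasa_points)
    sasa_l = accessible_surface_area(ligand, n_points=sasa_points)
    sasa_unbound = np.empty(complex_.n_atoms)
    sasa_unbound[receptor_sel.indices] = sasa_r
    sasa_unbound[ligand_sel.indices] = sasa_l
    dsasa_atom = sasa_cplx - sasa_unbound
    dsasa_res = {k: float(dsasa_atom[idx].sum()) for k, idx in res_of.items()}

    records = []
    vdw_by_pair: dict[tuple, float] = {}
    for r, l in pairs:
        ia, ib = res_of[r], res_of[l]
        e_coul = coulomb_energy(complex_, pairs=(ia, ib), dielectric=eps_in)
        e_gb = _gb_cross_term(complex_, radii, ia, ib, eps_in, eps_out)
        e_vdw = lennard_jones_energy(complex_, pairs=(ia, ib))
        vdw_by_pair[(r, l)] = e_vdw
        records.append({"receptor_residue": r, "ligand_residue": l,
                        "polar": e_coul + e_gb, "vdw": e_vdw})

    # attribute each residue's surface term once across the table
    surf_by_pair = {key: 0.0 for key in vdw_by_pair}
    partners_of: dict[tuple, list[tuple]] = {}
    for r, l in vdw_by_pair:
        partners_of.setdefault(r, []).append((r, l))
        partners_of.setdefault(l, []).append((r, l))
    for res, plist in partners_of.items():
        term = m.gamma * dsasa_res[res]
        if surface_attribution == "even-split":
            for key in plist:
                surf_by_pair[key] += term / len(plist)
        elif surface_attribution == "max-vdw":
            best = max(plist, key=lambda key: (abs(vdw_by_pair[key]), key))
            surf_by_pair[best] += term
        else:
            raise ValueError(f"unknown surface_attribution {surface_attribution!r}")

    for rec in records:
        key = (rec["receptor_residue"], rec["ligand_residue"])
        rec["nonpolar"] = rec.pop("vdw") + surf_by_pair[key]
        rec["total"] = rec["polar"] + rec["nonpolar"]
    return PairInteractionTable(rows=pd.DataFrame(records))


# ---------------------------------------------------------------------------
# Contact and hydrogen-bond probability maps
# ---------------------------------------------------------------------------

def _moiety_indices(s: MolecularStructure, residue: tuple[str, int], moiety: str) -> np.ndarray:
    sl = s.residue_index[residue]
    idx = np.arange(sl.start, sl.stop)
    heavy = s.heavy_mask[idx]
    mc = s.is_mainchain[idx]
    keep = heavy & (mc if moiety == "mc" else ~mc)
    return idx[keep]


def contact_probability_maps(
    ensemble: ConformationEnsemble,
    receptor_residues: list[tuple[str, int]],
    ligand_residues: list[tuple[str, int]],
    threshold: float = DEFAULT_CONTACT_THRESHOLD,
) -> ContactProbabilityMaps:
    """Moiety-contact occupancy maps over a trajectory.

    A contact exists in a frame when the geometric centers of the two
    heavy-atom moieties (mainchain or side chain) are closer than
    ``threshold``. Residues with an empty moiety (glycine-like side
    chains) are flagged undefined and reported as 0%.
    """
    if ensemble.n_frames == 0:
        raise ValueError("empty ensemble")
    topo = ensemble.topology
    pairings = [("sc", "sc"), ("mc", "mc"), ("sc", "mc"), ("mc", "sc")]
    maps = {}
    undefined = {}
    for rm, lm in pairings:
        key = f"{rm}-{lm}"
        r_idx = [_moiety_indices(topo, r, rm) for r in receptor_residues]
        l_idx = [_moiety_indices(topo, l, lm) for l in ligand_residues]
        count = np.zeros((len(receptor_residues), len(ligand_residues)))
        undef = np.zeros_like(count, dtype=bool)
        for a, ri in enumerate(r_idx):
            for b, li in enumerate(l_idx):
                if len(ri) == 0 or len(li) == 0:
                    undef[a, b] = True
        for f in range(ensemble.n_frames):
            coords = ensemble.frames[f]
            rc = [coords[ri].mean(axis=0) if len(ri) else None for ri in r_idx]
            lc = [coords[li].mean(axis=0) if len(li) else None for li in l_idx]
            for a, ca in enumerate(rc):
                if ca is None:
                    continue
                for b, cb in enumerate(lc):
                    if cb is None:
                        continue
                    if np.linalg.norm(ca - cb) < threshold:
                        count[a, b] += 1
        maps[key] = 100.0 * count / ensemble.n_frames
        undefined[key] = undef
    return ContactProbabilityMaps(
        receptor_residues=receptor_residues,
        ligand_residues=ligand_residues,
        maps=maps,
        undefined=undefined,
    )


def _attached_hydrogens(s: MolecularStructure, donor: int, max_bond: float = 1.3) -> np.ndarray:
    h_idx = np.nonzero(~s.heavy_mask)[0]
    if h_idx.size == 0:
        return h_idx
    d = np.linalg.norm(s.coords[h_idx] - s.coords[donor], axis=1)
    return h_idx[d <= max_bond]


def _antecedent(s: MolecularStructure, donor: int, max_bond: float = 1.8) -> int | None:
    heavy = np.nonzero(s.heavy_mask)[0]
    heavy = heavy[heavy != donor]
    if heavy.size == 0:
        return None
    d = np.linalg.norm(s.coords[heavy] - s.coords[donor], axis=1)
    near = heavy[d <= max_bond]
    if near.size == 0:
        return None
    return int(near[np.argmin(d[d <= max_bond])])


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    v1, v2 = a - b, c - b
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2) + 1e-12)
    return float(np.degrees(np.arccos(np.clip(cosang, -1, 1))))


def hbond_probability_map(
    ensemble: ConformationEnsemble,
    catalogue: list[tuple[int, int]],
    d_max: float = DEFAULT_HBOND_DMAX,
    angle_min: float = DEFAULT_HBOND_ANGLE_MIN,
) -> HBondProbabilityMap:
    """Hydrogen-bond occupancy per (donor atom, acceptor atom) pair.

    Present in a frame when the donor-acceptor heavy-atom distance is
    below ``d_max`` AND some donor hydrogen gives a D-H...A angle above
    ``angle_min``. When the donor carries no hydrogen in the topology,
    the angle gate falls back to the antecedent-D-A pseudo-angle and the
    pair is flagged ``angle_waived``.
    """
    if not catalogue:
        raise ValueError("empty donor/acceptor catalogue")
    topo = ensemble.topology
    occupancy: dict[tuple[str, str], float] = {}
    waived: set[tuple[str, str]] = set()

    def atom_tag(i: int) -> str:
        return f"{topo.chain_ids[i]}:{topo.residue_names[i]}{topo.residue_ids[i]}:{topo.names[i]}"

    for donor, acceptor in catalogue:
        hydrogens = _attached_hydrogens(topo, donor)
        use_proxy = hydrogens.size == 0
        antecedent = _antecedent(topo, donor) if use_proxy else None
        tag = (atom_tag(donor), atom_tag(acceptor))
        hits = 0
        for f in range(ensemble.n_frames):
            coords = ensemble.frames[f]
            d = np.linalg.norm(coords[donor] - coords[acceptor])
            if d >= d_max:
                continue
            if use_proxy:
                if antecedent is None:
                    hits += 1  # bare donor: distance criterion only
                    continue
                ang = _angle_deg(coords[antecedent], coords[donor], coords[acceptor])
                if ang > angle_min:
                    hits += 1
            else:
                for h in hydrogens:
                    if _angle_deg(coords[donor], coords[h], coords[acceptor]) > angle_min:
                        hits += 1
                        break
        occupancy[tag] = 100.0 * hits / ensemble.n_frames
        if use_proxy:
            waived.add(tag)
    return HBondProbabilityMap(occupancy=occupancy, angle_waived=waived)
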