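"""Implicit-solvent energetics with a slab membrane.

Molecular-mechanics nonbonded terms (Coulomb, Lennard-Jones), numerical
solvent-accessible surface areas, a pairwise-descreening generalized-Born
model with a membrane slab switching function, a finite-difference
linearized Poisson solver on a dielectric map with the same slab, and a
steepest-descent minimizer.

Membrane model
--------------
The membrane is an infinite slab of low dielectric normal to z, centered
at z = 0. For the GB model, solvent screening of each atom is attenuated
by the switching function S(z): S = 0 for |z| <= T_memb/2 - l_msw
(fully buried), S = 1 for |z| >= T_memb/2 + l_msw (fully solvated), and a
smooth cubic in between. S rescales the atom's inverse Born radius, so a
buried atom's effective Born radius grows toward the (capped) burial
limit and its solvation vanishes. Defaults T_memb = 36 A, l_msw = 2.5 A.
For the PB model, the slab enters the dielectric map directly: epsilon =
eps_protein inside atom spheres, eps_membrane in |z| <= pb_slab/2 outside
the solute (default 31 A thickness, eps 1), eps_water (80) elsewhere.

The nonpolar solvation term is gamma * SASA with gamma = 0.04
kcal/(mol A^2) by default.

This GB model is a documented pairwise-descreening (HCT-style) slab GB
sharing the membrane parameters above; it is not a reimplementation of
any particular MD package's membrane GB.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import cg

from .core import MolecularStructure, ParameterError

__all__ = [
    "COULOMB_K",
    "MembraneModel",
    "AQUEOUS",
    "GridSpec",
    "EnergyBreakdown",
    "BornRadiiSet",
    "membrane_switch",
    "coulomb_energy",
    "lennard_jones_energy",
    "accessible_surface_area",
    "effective_born_radii",
    "gb_solvation_energy",
    "pb_solvation_energy",
    "nonpolar_surface_energy",
    "steepest_descent_minimize",
]

#: Electrostatic conversion constant, kcal*A/(mol*e^2). Fixed for
#: bit-reproducibility.
COULOMB_K = 332.0716

_BORN_RADIUS_CAP = 1.0e4  # A; keeps buried-atom Born radii finite


@dataclass(frozen=True)
class MembraneModel:
    """Slab-membrane parameters (see module docstring for semantics).

    ``eps_protein`` is the solute-interior dielectric of the PB map
    (default 2); ``eps_mm_interior`` is the interior dielectric of the
    GB/MM terms (default 1).
    """

    t_memb: float = 36.0
    l_msw: float = 2.5
    gamma: float = 0.04
    eps_protein: float = 2.0
    eps_mm_interior: float = 1.0
    eps_membrane: float = 1.0
    eps_water: float = 80.0
    pb_slab_thickness: float = 31.0

    def __post_init__(self):
        if self.t_memb <= 0 or self.pb_slab_thickness <= 0:
            raise ValueError("slab thicknesses must be positive")
        if min(self.eps_protein, self.eps_membrane, self.eps_water, self.eps_mm_interior) < 1:
            raise ValueError("dielectric constants must be >= 1")
        if not self.l_msw < self.t_memb / 2:
            raise ValueError("l_msw must be smaller than t_memb/2")


#: Sentinel geometry for aqueous (no-membrane) solvation contexts.
AQUEOUS = None


@dataclass(frozen=True)
class GridSpec:
    """Finite-difference grid: node counts, spacing (A) and center."""

    n_points: tuple[int, int, int] = (150, 150, 150)
    spacing: float = 0.5
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        object.__setattr__(self, "n_points", tuple(int(n) for n in self.n_points))
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))
        if any(n < 33 for n in self.n_points):
            raise ValueError("grid needs >= 33 points per axis")
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.center[d] + self.spacing * (np.arange(self.n_points[d]) - (self.n_points[d] - 1) / 2)
            for d in range(3)
        )


@dataclass
class EnergyBreakdown:
    """Component-resolved energies, kcal/mol; ``total`` sums what is set."""

    coulomb: float = 0.0
    vdw: float = 0.0
    gb_solvation: float = 0.0
    pb_solvation: float | None = None
    nonpolar_surface: float = 0.0

    @property
    def total(self) -> float:
        solv = self.pb_solvation if self.pb_solvation is not None else self.gb_solvation
        return self.coulomb + self.vdw + solv + self.nonpolar_surface


@dataclass
class BornRadiiSet:
    radii: np.ndarray  # per-atom effective Born radius, A
    context_label: str = ""

    def __post_init__(self):
        self.radii = np.asarray(self.radii, dtype=float)
        if not np.all(np.isfinite(self.radii)):
            raise ValueError("non-finite Born radii")


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------

def _require(values: np.ndarray, what: str, positive: bool = False) -> None:
    bad = ~np.isfinite(values) | ((values <= 0) if positive else np.zeros_like(values, dtype=bool))
    if np.any(bad):
        raise ParameterError(f"missing {what} for atom index {int(np.nonzero(bad)[0][0])}")


def _pair_lists(s: MolecularStructure, pairs) -> tuple[np.ndarray, np.ndarray]:
    """Resolve a pair specification to two index arrays (i < j for 'all')."""
    n = s.n_atoms
    if isinstance(pairs, str) and pairs == "all":
        iu, ju = np.triu_indices(n, k=1)
        return iu, ju
    a, b = pairs
    a = np.asarray(a, dtype=int)
    b = np.asarray(b, dtype=int)
    ii, jj = np.meshgrid(a, b, indexing="ij")
    return ii.ravel(), jj.ravel()


def membrane_switch(z: np.ndarray, m: MembraneModel) -> np.ndarray:
    """Slab switching function S(z) in [0, 1]; 0 = buried, 1 = solvated."""
    az = np.abs(np.asarray(z, dtype=float))
    lo = m.t_memb / 2 - m.l_msw
    u = np.clip((az - lo) / (2 * m.l_msw), 0.0, 1.0)
    return u * u * (3 - 2 * u)


# ---------------------------------------------------------------------------
# Molecular-mechanics terms
# ---------------------------------------------------------------------------

def coulomb_energy(s: MolecularStructure, pairs="all", dielectric: float = 1.0) -> float:
    """Coulomb energy k * q_i q_j / (eps * r_ij) summed over the pair set."""
    _require(s.charges, "charge")
    i, j = _pair_lists(s, pairs)
    r = np.linalg.norm(s.coords[i] - s.coords[j], axis=1)
    charged = (s.charges[i] != 0) & (s.charges[j] != 0)
    if np.any((r < 1e-8) & charged):
        raise ValueError("coincident charged atoms")
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(r > 1e-8, COULOMB_K * s.charges[i] * s.charges[j] / (dielectric * r), 0.0)
    return float(e.sum())


def lennard_jones_energy(s: MolecularStructure, pairs="all", cutoff: float | None = None) -> float:
    """12-6 Lennard-Jones energy with CHARMM-style combination rules.

    eps_ij = sqrt(eps_i eps_j), rmin_ij = rmin_half_i + rmin_half_j;
    E = eps_ij [ (rmin/r)^12 - 2 (rmin/r)^6 ]. ``cutoff`` (A) truncates
    the pair list (default: none, matching rigid rescoring; 16 A mirrors
    the simulation-style cutoff).
    """
    _require(s.lj_epsilon, "LJ epsilon")
    _require(s.lj_rmin_half, "LJ rmin/2", positive=True)
    i, j = _pair_lists(s, pairs)
    r = np.linalg.norm(s.coords[i] - s.coords[j], axis=1)
    if np.any(r < 1e-8):
        raise ValueError("zero interatomic distance in LJ")
    if cutoff is not None:
        keep = r <= cutoff
        i, j, r = i[keep], j[keep], r[keep]
    eps = np.sqrt(s.lj_epsilon[i] * s.lj_epsilon[j])
    rmin = s.lj_rmin_half[i] + s.lj_rmin_half[j]
    x6 = (rmin / r) ** 6
    return float(np.sum(eps * (x6 * x6 - 2 * x6)))


def accessible_surface_area(
    s: MolecularStructure, probe: float = 1.4, n_points: int = 960
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (A^2), heavy atoms only.

    Numerical Shrake-Rupley quadrature on a deterministic Fibonacci point
    set (via biotite), with the per-atom solvation radii. Hydrogens get
    zero area and do not occlude.
    """
    import biotite.structure as struc

    heavy = np.nonzero(s.heavy_mask)[0]
    radii = s.solvation_radius[heavy]
    if np.any(~np.isfinite(radii) | (radii <= 0)):
        raise ParameterError("missing solvation radius for SASA")
    arr = struc.AtomArray(len(heavy))
    arr.coord = s.coords[heavy].astype(np.float32)
    arr.atom_name = s.names[heavy].astype("U6")
    arr.element = s.elements[heavy].astype("U2")
    arr.res_name = s.residue_names[heavy].astype("U5")
    arr.res_id = s.residue_ids[heavy]
    arr.chain_id = s.chain_ids[heavy].astype("U4")
    areas_heavy = struc.sasa(
        arr,
        probe_radius=probe,
        point_number=n_points,
        vdw_radii=radii.astype(float),
        ignore_ions=False,
    )
    areas = np.zeros(s.n_atoms)
    areas[heavy] = np.nan_to_num(areas_heavy)
    return areas


def nonpolar_surface_energy(areas: np.ndarray, gamma: float = 0.04) -> float:
    """Surface-tension nonpolar term: gamma * sum of areas (kcal/mol)."""
    areas = np.asarray(areas, dtype=float)
    if np.any(areas < 0):
        raise ValueError("negative surface area")
    return float(gamma * areas.sum())


# ---------------------------------------------------------------------------
# Generalized Born
# ---------------------------------------------------------------------------

def _hct_integral(r: np.ndarray, rho_i: np.ndarray, rho_j: np.ndarray) -> np.ndarray:
    """Pairwise descreening integral of atom j's sphere seen from atom i.

    Closed form of (1/4pi) * Int_{sphere j} dV / s^4 outside radius rho_i,
    for a sphere of radius rho_j at center distance r.
    """
    r = np.asarray(r, dtype=float)
    out = np.zeros_like(r)
    active = r + rho_j > rho_i  # otherwise sphere j is engulfed by i
    if not np.any(active):
        return out
    r_, pi, pj = r[active], np.broadcast_to(rho_i, r.shape)[active], np.broadcast_to(rho_j, r.shape)[active]
    L = np.maximum(np.abs(r_ - pj), pi)
    U = r_ + pj
    term = (
        1.0 / L
        - 1.0 / U
        + (r_ / 4.0) * (1.0 / U**2 - 1.0 / L**2)
        + (1.0 / (2.0 * r_)) * np.log(L / U)
        + (pj**2 / (4.0 * r_)) * (1.0 / L**2 - 1.0 / U**2)
    )
    engulfing = pj - r_ > pi  # atom i inside sphere j
    term = term + np.where(engulfing, 2.0 * (1.0 / pi - 1.0 / L), 0.0)
    out[active] = 0.5 * term
    return out


def effective_born_radii(s: MolecularStructure, m: MembraneModel | None = AQUEOUS) -> BornRadiiSet:
    """Effective Born radii by pairwise descreening (heavy + H alike).

    In membrane mode the inverse Born radius is rescaled by the slab
    switch S(z): fully buried atoms approach the (capped) desolvated
    limit. The aqueous mode is S = 1 everywhere.
    """
    _require(s.solvation_radius, "solvation radius", positive=True)
    rho = s.solvation_radius
    n = s.n_atoms
    inv = 1.0 / rho
    if n > 1:
        iu, ju = np.triu_indices(n, k=1)
        r = np.linalg.norm(s.coords[iu] - s.coords[ju], axis=1)
        contrib_ij = _hct_integral(r, rho[iu], rho[ju])  # j descreens i
        contrib_ji = _hct_integral(r, rho[ju], rho[iu])  # i descreens j
        np.subtract.at(inv, iu, contrib_ij)
        np.subtract.at(inv, ju, contrib_ji)
    inv = np.maximum(inv, 1.0 / _BORN_RADIUS_CAP)
    context = "aqueous"
    if m is not AQUEOUS:
        inv = np.maximum(inv * membrane_switch(s.coords[:, 2], m), 1.0 / _BORN_RADIUS_CAP)
        context = "membrane"
    return BornRadiiSet(radii=1.0 / inv, context_label=context)


def gb_solvation_energy(
    s: MolecularStructure,
    radii: BornRadiiSet,
    m: MembraneModel | None = AQUEOUS,
    charge_mask: np.ndarray | None = None,
    eps_in: float | None = None,
    eps_out: float | None = None,
) -> float:
    """Generalized-Born polar solvation energy (kcal/mol).

    E = -(k/2)(1/eps_in - 1/eps_out) * sum_ij q_i q_j / f_GB with the
    canonical interpolation f_GB = sqrt(r^2 + a_i a_j exp(-r^2/(4 a_i a_j))).
    ``charge_mask`` zeroes the charges of atoms outside the subset while
    keeping the Born radii fixed (the decomposition convention).
    """
    _require(s.charges, "charge")
    model = m if m is not AQUEOUS else MembraneModel()
    e_in = eps_in if eps_in is not None else model.eps_mm_interior
    e_out = eps_out if eps_out is not None else model.eps_water
    q = s.charges.copy()
    if charge_mask is not None:
        mask = np.zeros(s.n_atoms, dtype=bool)
        mask[np.asarray(charge_mask, dtype=int)] = True
        q = np.where(mask, q, 0.0)
    if not np.any(q != 0):
        warnings.warn("no charged atoms selected; GB energy is 0", stacklevel=2)
        return 0.0
    a = radii.radii
    dx = s.coords[:, None, :] - s.coords[None, :, :]
    r2 = np.sum(dx * dx, axis=-1)
    aa = a[:, None] * a[None, :]
    f = np.sqrt(r2 + aa * np.exp(-r2 / (4.0 * aa)))
    qq = q[:, None] * q[None, :]
    pref = -0.5 * COULOMB_K * (1.0 / e_in - 1.0 / e_out)
    return float(pref * np.sum(qq / f))


# ---------------------------------------------------------------------------
# Finite-difference Poisson solver
# ---------------------------------------------------------------------------

def _dielectric_at(points: np.ndarray, s, m: MembraneModel, mode: str, eps_in: float) -> np.ndarray:
    """Dielectric at arbitrary points: solute interior, slab, or water."""
    eps = np.full(len(points), m.eps_water)
    if mode == "membrane":
        eps[np.abs(points[:, 2]) <= m.pb_slab_thickness / 2] = m.eps_membrane
    rho = s.solvation_radius
    inside = np.zeros(len(points), dtype=bool)
    for c, radius in zip(s.coords, rho):
        d2 = np.sum((points - c) ** 2, axis=1)
        inside |= d2 < radius * radius
    eps[inside] = eps_in
    return eps


def _face_dielectrics(g: GridSpec, s, m: MembraneModel, mode: str, eps_in: float):
    xs, ys, zs = g.axes()
    faces = []
    for axis in range(3):
        ax = [xs, ys, zs]
        ax[axis] = 0.5 * (ax[axis][:-1] + ax[axis][1:])
        grid = np.meshgrid(*ax, indexing="ij")
        pts = np.stack([a.ravel() for a in grid], axis=1)
        if mode == "uniform":
            eps = np.full(len(pts), eps_in)
        else:
            eps = _dielectric_at(pts, s, m, mode, eps_in)
        faces.append(eps.reshape(grid[0].shape))
    return faces


def _spread_charges(g: GridSpec, s) -> np.ndarray:
    """Trilinear charge assignment to grid nodes (units: e)."""
    xs, ys, zs = g.axes()
    n = g.n_points
    q_grid = np.zeros(n)
    frac = np.stack(
        [
            (s.coords[:, d] - (g.center[d] - g.spacing * (n[d] - 1) / 2)) / g.spacing
            for d in range(3)
        ],
        axis=1,
    )
    i0 = np.floor(frac).astype(int)
    if np.any(i0 < 0) or np.any(i0 + 1 > np.array(n) - 1):
        raise ValueError("solute charge outside the PB grid")
    w = frac - i0
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                weight = (
                    (w[:, 0] if dx else 1 - w[:, 0])
                    * (w[:, 1] if dy else 1 - w[:, 1])
                    * (w[:, 2] if dz else 1 - w[:, 2])
                )
                np.add.at(q_grid, (i0[:, 0] + dx, i0[:, 1] + dy, i0[:, 2] + dz), s.charges * weight)
    return q_grid


def _boundary_potential_plane(points: np.ndarray, s, eps_bc: float) -> np.ndarray:
    phi = np.zeros(len(points))
    for c, q in zip(s.coords, s.charges):
        if q == 0:
            continue
        r = np.linalg.norm(points - c, axis=1)
        phi += COULOMB_K * q / (eps_bc * np.maximum(r, 1e-6))
    return phi


def _solve_grid(g: GridSpec, faces, q_grid: np.ndarray, s, eps_bc: float, tol: float, maxiter: int):
    """Solve the 7-point variable-coefficient Poisson system for interior
    nodes with Dirichlet (Coulomb/eps_bc) boundary values; returns the
    interior potential in kcal/(mol e)."""
    nx, ny, nz = g.n_points
    h = g.spacing
    ex, ey, ez = faces
    exm = ex[0 : nx - 2, 1 : ny - 1, 1 : nz - 1]
    exp_ = ex[1 : nx - 1, 1 : ny - 1, 1 : nz - 1]
    eym = ey[1 : nx - 1, 0 : ny - 2, 1 : nz - 1]
    eyp = ey[1 : nx - 1, 1 : ny - 1, 1 : nz - 1]
    ezm = ez[1 : nx - 1, 1 : ny - 1, 0 : nz - 2]
    ezp = ez[1 : nx - 1, 1 : ny - 1, 1 : nz - 1]
    mx, my, mz = nx - 2, ny - 2, nz - 2
    n_unknown = mx * my * mz
    diag = (exm + exp_ + eym + eyp + ezm + ezp).ravel()
    b = 4.0 * np.pi * COULOMB_K * q_grid[1:-1, 1:-1, 1:-1].ravel() / h

    xs, ys, zs = g.axes()

    def plane(axis: int, index: int) -> np.ndarray:
        ax = [xs[1:-1], ys[1:-1], zs[1:-1]]
        ax[axis] = np.array([(xs, ys, zs)[axis][index]])
        grid = np.meshgrid(*ax, indexing="ij")
        pts = np.stack([a.ravel() for a in grid], axis=1)
        shape = tuple(len(a) for a in ax)
        return _boundary_potential_plane(pts, s, eps_bc).reshape(shape).squeeze(axis)

    # off-diagonals (zeroed where the neighbour is a boundary node, whose
    # known potential moves to the rhs)
    def offdiag(face_arr, axis, side):
        a = (-face_arr).copy()
        sl = [slice(None)] * 3
        sl[axis] = -1 if side > 0 else 0
        a[tuple(sl)] = 0.0
        return a.ravel()

    bc = b.reshape(mx, my, mz)
    bc[0, :, :] += exm[0, :, :] * plane(0, 0)
    bc[-1, :, :] += exp_[-1, :, :] * plane(0, nx - 1)
    bc[:, 0, :] += eym[:, 0, :] * plane(1, 0)
    bc[:, -1, :] += eyp[:, -1, :] * plane(1, ny - 1)
    bc[:, :, 0] += ezm[:, :, 0] * plane(2, 0)
    bc[:, :, -1] += ezp[:, :, -1] * plane(2, nz - 1)
    b = bc.ravel()

    strides = (my * mz, mz, 1)
    diagonals = [diag]
    offsets = [0]
    for face_arr, axis in ((exp_, 0), (eyp, 1), (ezp, 2)):
        arr = offdiag(face_arr, axis, +1)
        diagonals.append(arr[: n_unknown - strides[axis]])
        offsets.append(strides[axis])
    for face_arr, axis in ((exm, 0), (eym, 1), (ezm, 2)):
        arr = offdiag(face_arr, axis, -1)
        diagonals.append(arr[strides[axis]:])
        offsets.append(-strides[axis])
    A = sparse.diags_array(diagonals, offsets=offsets, format="csr")

    # Preconditioner: exact inverse of the unit-coefficient 7-point
    # Dirichlet Laplacian via 3D discrete sine transforms. The map
    # operator differs from it only through the (bounded) dielectric
    # contrast, so preconditioned CG converges in a few dozen iterations.
    if np.ptp(np.concatenate([e.ravel() for e in faces])) == 0.0:
        eps_const = float(faces[0].flat[0])
        phi = _dst_poisson_solve(b.reshape(mx, my, mz), eps_const).ravel()
        res = float(np.linalg.norm(A @ phi - b) / max(np.linalg.norm(b), 1e-30))
        if np.linalg.norm(b) > 0 and res > max(tol * 10, 1e-8):
            raise RuntimeError(f"uniform PB solve inconsistent (residual {res:.2e})")
        return phi.reshape(mx, my, mz)

    shape = (mx, my, mz)
    M = sparse.linalg.LinearOperator(
        (n_unknown, n_unknown),
        matvec=lambda v: _dst_poisson_solve(v.reshape(shape), 1.0).ravel(),
    )
    phi, info = cg(A, b, rtol=tol, atol=0.0, maxiter=maxiter, M=M)
    if info != 0:
        res = float(np.linalg.norm(A @ phi - b) / np.linalg.norm(b))
        raise RuntimeError(f"PB solver did not converge (relative residual {res:.2e})")
    return phi.reshape(mx, my, mz)


def _dst_poisson_solve(rhs: np.ndarray, eps_const: float) -> np.ndarray:
    """Solve the constant-coefficient 7-point Dirichlet system exactly.

    The homogeneous-Dirichlet eigenvectors of the discrete Laplacian are
    sine modes, so the solve is three forward DST-I transforms, a
    spectral division, and the inverse transforms.
    """
    from scipy.fft import dstn, idstn

    m = rhs.shape
    lam = 0.0
    for axis, n in enumerate(m):
        k = np.arange(1, n + 1)
        shape1 = [1, 1, 1]
        shape1[axis] = n
        lam = lam + (2.0 - 2.0 * np.cos(np.pi * k / (n + 1))).reshape(shape1)
    spec = dstn(rhs, type=1)
    return idstn(spec / (eps_const * lam), type=1)


def _grid_energy(phi_int: np.ndarray, q_grid: np.ndarray) -> float:
    return float(0.5 * np.sum(q_grid[1:-1, 1:-1, 1:-1] * phi_int))


def pb_solvation_energy(
    s: MolecularStructure,
    g: GridSpec = GridSpec(),
    m: MembraneModel | None = AQUEOUS,
    mode: str | None = None,
    eps_in: float | None = None,
    tol: float = 1e-6,
    maxiter: int = 5000,
) -> float:
    """Electrostatic solvation energy from the finite-difference Poisson
    equation (linearized, zero ionic strength) on a dielectric map.

    The solvation energy is the grid energy with the dielectric map minus
    the grid energy of a uniform-``eps_in`` reference solve on the same
    grid, which cancels the spread-charge self energy. ``mode`` is
    "membrane" or "aqueous" (inferred from ``m`` when omitted).
    """
    _require(s.charges, "charge")
    _require(s.solvation_radius, "solvation radius", positive=True)
    model = m if m is not AQUEOUS else MembraneModel()
    if mode is None:
        mode = "membrane" if m is not AQUEOUS else "aqueous"
    e_in = eps_in if eps_in is not None else model.eps_protein

    half = np.array([(n - 1) / 2 * g.spacing for n in g.n_points])
    lo = np.array(g.center) - half
    hi = np.array(g.center) + half
    pad = np.minimum(
        (s.coords - s.solvation_radius[:, None] - lo).min(axis=0).min(),
        (hi - s.coords - s.solvation_radius[:, None]).min(axis=0).min(),
    )
    if pad < 0:
        raise ValueError("solute (with radii) extends outside the PB grid")
    if pad < 5.0:
        warnings.warn(f"solute within {pad:.1f} A of the PB grid edge (< 5 A padding)", stacklevel=2)

    q_grid = _spread_charges(g, s)
    faces = _face_dielectrics(g, s, model, mode, e_in)
    phi = _solve_grid(g, faces, q_grid, s, model.eps_water if mode != "uniform" else e_in, tol, maxiter)
    e_map = _grid_energy(phi, q_grid)

    faces_ref = _face_dielectrics(g, s, model, "uniform", e_in)
    phi_ref = _solve_grid(g, faces_ref, q_grid, s, e_in, tol, maxiter)
    e_ref = _grid_energy(phi_ref, q_grid)
    return e_map - e_ref


# ---------------------------------------------------------------------------
# Steepest-descent minimizer
# ---------------------------------------------------------------------------

def _mm_energy_forces(
    coords: np.ndarray,
    s: MolecularStructure,
    dielectric: float,
    excluded: set[tuple[int, int]],
) -> tuple[float, np.ndarray]:
    n = len(coords)
    iu, ju = np.triu_indices(n, k=1)
    if excluded:
        keep = np.array([(int(a), int(b)) not in excluded for a, b in zip(iu, ju)])
        iu, ju = iu[keep], ju[keep]
    d = coords[iu] - coords[ju]
    r2 = np.sum(d * d, axis=1)
    r = np.sqrt(r2)
    if np.any(r < 1e-6):
        raise FloatingPointError("near-singular contact")
    qq = COULOMB_K * s.charges[iu] * s.charges[ju] / dielectric
    e_coul = qq / r
    eps = np.sqrt(s.lj_epsilon[iu] * s.lj_epsilon[ju])
    rmin = s.lj_rmin_half[iu] + s.lj_rmin_half[ju]
    x6 = (rmin / r) ** 6
    e_lj = eps * (x6 * x6 - 2 * x6)
    # dE/dr terms
    de = -qq / r2 + eps * (-12 * x6 * x6 + 12 * x6) / r
    fpair = (-de / r)[:, None] * d  # force on atom iu
    forces = np.zeros_like(coords)
    np.add.at(forces, iu, fpair)
    np.add.at(forces, ju, -fpair)
    return float(e_coul.sum() + e_lj.sum()), forces


def steepest_descent_minimize(
    s: MolecularStructure,
    n_steps: int = 100,
    dielectric: float = 4.0,
    step_size: float = 0.02,
    fixed: np.ndarray | None = None,
    excluded_pairs: list[tuple[int, int]] | None = None,
    return_trajectory: bool = False,
):
    """Adaptive steepest descent on Coulomb(eps) + LJ.

    The accepted-step energy is non-increasing: a trial step along the
    normalized force is accepted only if it lowers the energy, otherwise
    the step size is halved (and grown by 1.2x after acceptance).
    ``fixed`` atoms keep their coordinates. ``excluded_pairs`` lists
    bonded (i, j) pairs omitted from the nonbonded sums.
    """
    _require(s.charges, "charge")
    _require(s.lj_epsilon, "LJ epsilon")
    excluded = {tuple(sorted(p)) for p in (excluded_pairs or [])}
    coords = s.coords.copy()
    fixed_mask = np.zeros(s.n_atoms, dtype=bool)
    if fixed is not None:
        fixed_mask[np.asarray(fixed, dtype=int)] = True
    energy, forces = _mm_energy_forces(coords, s, dielectric, excluded)
    history = [energy]
    step = step_size
    failures = 0
    for _ in range(n_steps):
        forces[fixed_mask] = 0.0
        fmax = np.abs(forces).max()
        if fmax < 1e-10 or step < 1e-12:
            break
        trial = coords + step * forces / fmax
        try:
            e_new, f_new = _mm_energy_forces(trial, s, dielectric, excluded)
            ok = np.isfinite(e_new) and e_new <= energy
        except FloatingPointError:
            ok = False
            failures += 1
            if failures > 60:
                raise RuntimeError("minimization failed: persistent singular contacts")
        if ok:
            coords, energy, forces = trial, e_new, f_new
            step *= 1.2
        else:
            step *= 0.5
        history.append(energy)
    out = s.with_coords(coords)
    if return_trajectory:
        return out, history
    return out
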