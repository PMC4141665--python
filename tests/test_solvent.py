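"""Implicit-solvent energetics: MM terms, SASA, GB, PB and the minimizer."""

import numpy as np
import pytest

from posesieve import (
    AQUEOUS,
    COULOMB_K,
    GridSpec,
    MembraneModel,
    accessible_surface_area,
    coulomb_energy,
    effective_born_radii,
    gb_solvation_energy,
    lennard_jones_energy,
    membrane_switch,
    nonpolar_surface_energy,
    pb_solvation_energy,
    steepest_descent_minimize,
)
from posesieve.core import MolecularStructure
from posesieve.fixtures import make_born_system

BORN_ANALYTIC = -0.5 * COULOMB_K * (1 - 1 / 80.0) / 2.0  # q=1 e, a=2 A, eps 1->80


def charged_beads(coords, charges, radius=1.7, eps=0.12, rmin_half=1.9):
    n = len(coords)
    return MolecularStructure(
        names=[f"X{i}" for i in range(n)],
        elements=["C"] * n,
        residue_names=["GLY"] * n,
        residue_ids=list(range(1, n + 1)),
        chain_ids=["A"] * n,
        coords=np.asarray(coords, dtype=float),
        charges=np.asarray(charges, dtype=float),
        lj_epsilon=np.full(n, eps),
        lj_rmin_half=np.full(n, rmin_half),
        solvation_radius=np.full(n, radius),
    )


class TestCoulomb:
    def test_unit_charges_at_unit_distance(self):
        s = charged_beads([[0, 0, 0], [1, 0, 0]], [1, 1])
        assert coulomb_energy(s, dielectric=1.0) == pytest.approx(332.0716)
        assert coulomb_energy(s, dielectric=4.0) == pytest.approx(83.0179)

    def test_matches_bruteforce_loop(self, rng):
        coords = rng.uniform(-4, 4, (5, 3))
        charges = rng.uniform(-1, 1, 5)
        s = charged_beads(coords, charges)
        expected = 0.0
        for i in range(5):
            for j in range(i + 1, 5):
                expected += COULOMB_K * charges[i] * charges[j] / np.linalg.norm(coords[i] - coords[j])
        assert coulomb_energy(s) == pytest.approx(expected, abs=1e-10)

    def test_coincident_charges_rejected(self):
        s = charged_beads([[0, 0, 0], [0, 0, 0]], [1, 1])
        with pytest.raises(ValueError, match="coincident"):
            coulomb_energy(s)

    def test_rigid_motion_invariance(self, rng):
        from scipy.spatial.transform import Rotation

        coords = rng.uniform(-4, 4, (6, 3))
        charges = rng.uniform(-1, 1, 6)
        s = charged_beads(coords, charges)
        ref = coulomb_energy(s)
        moved = s.with_coords(Rotation.random(random_state=3).apply(coords) + [10, -4, 2])
        assert coulomb_energy(moved) == pytest.approx(ref, abs=1e-6)


class TestLennardJones:
    def test_minimum_and_asymptote(self):
        s = charged_beads([[0, 0, 0], [3.8, 0, 0]], [0, 0])  # r = rmin_ij
        assert lennard_jones_energy(s) == pytest.approx(-0.12)
        far = charged_beads([[0, 0, 0], [500.0, 0, 0]], [0, 0])
        assert lennard_jones_energy(far) == pytest.approx(0.0, abs=1e-10)

    def test_matches_bruteforce_loop(self, rng):
        coords = rng.uniform(-6, 6, (10, 3))
        s = charged_beads(coords, np.zeros(10))
        expected = 0.0
        for i in range(10):
            for j in range(i + 1, 10):
                r = np.linalg.norm(coords[i] - coords[j])
                x6 = (3.8 / r) ** 6
                expected += 0.12 * (x6 * x6 - 2 * x6)
        assert lennard_jones_energy(s) == pytest.approx(expected, rel=1e-12)

    def test_cutoff_truncates(self):
        s = charged_beads([[0, 0, 0], [20.0, 0, 0]], [0, 0])
        assert lennard_jones_energy(s, cutoff=16.0) == 0.0
        assert lennard_jones_energy(s) != 0.0


class TestSASA:
    def test_isolated_sphere_analytic(self):
        s = charged_beads([[0, 0, 0]], [0], radius=1.7)
        area = accessible_surface_area(s, probe=1.4).sum()
        assert area == pytest.approx(4 * np.pi * 3.1**2, rel=0.01)

    def test_far_separated_additivity(self):
        s = charged_beads([[0, 0, 0], [100.0, 0, 0]], [0, 0], radius=1.7)
        single = 4 * np.pi * 3.1**2
        assert accessible_surface_area(s).sum() == pytest.approx(2 * single, rel=0.01)

    def test_buried_atom_zero(self):
        # central atom enclosed by a dense shell of neighbours
        shell = []
        for theta in np.linspace(0, np.pi, 12):
            for phi in np.linspace(0, 2 * np.pi, 24, endpoint=False):
                shell.append(
                    2.2 * np.array([
                        np.sin(theta) * np.cos(phi),
                        np.sin(theta) * np.sin(phi),
                        np.cos(theta),
                    ])
                )
        coords = [[0.0, 0, 0]] + shell
        s = charged_beads(coords, np.zeros(len(coords)), radius=1.7)
        per_atom = accessible_surface_area(s)
        assert per_atom[0] == pytest.approx(0.0, abs=1e-9)

    def test_nonpolar_energy(self):
        assert nonpolar_surface_energy(np.array([40.0, 60.0]), gamma=0.04) == pytest.approx(4.0)
        assert nonpolar_surface_energy(np.zeros(3)) == 0.0
        with pytest.raises(ValueError):
            nonpolar_surface_energy(np.array([-1.0]))


def hct_quadrature(r, rho_i, rho_j, h=0.04):
    """Numerical volume integral (1/4pi) Int_{sphere j} dV / s^4, excluding
    the region inside rho_i -- an independent oracle for the descreening
    integral."""
    n = int(np.ceil(rho_j / h)) + 1
    g = np.arange(-n, n + 1) * h
    x, y, z = np.meshgrid(g, g, g, indexing="ij")
    inside = x**2 + y**2 + z**2 <= rho_j**2
    px = x[inside] + r  # sphere j centered at distance r along x
    py, pz = y[inside], z[inside]
    s2 = px**2 + py**2 + pz**2
    keep = s2 > rho_i**2
    return float(np.sum(1.0 / s2[keep] ** 2) * h**3 / (4 * np.pi))


class TestBornRadii:
    def test_isolated_atom_equals_intrinsic(self, born_ion):
        radii = effective_born_radii(born_ion, AQUEOUS)
        assert radii.radii[0] == pytest.approx(2.0, abs=1e-6)

    def test_buried_atom_effectively_desolvated(self, born_ion):
        m = MembraneModel()
        radii = effective_born_radii(born_ion, m)
        assert radii.radii[0] >= 10 * 2.0

    def test_two_atom_descreening_matches_quadrature(self):
        s = charged_beads([[0, 0, 0], [4.0, 0, 0]], [1, -1], radius=1.7)
        radii = effective_born_radii(s, AQUEOUS).radii
        integral = hct_quadrature(4.0, 1.7, 1.7)
        expected = 1.0 / (1.0 / 1.7 - integral)
        assert radii[0] == pytest.approx(expected, rel=2e-3)
        assert radii[1] == pytest.approx(expected, rel=2e-3)
        assert np.all(radii >= 1.7)

    def test_switch_profile(self):
        m = MembraneModel()
        assert membrane_switch(0.0, m) == 0.0
        assert membrane_switch(15.5, m) == 0.0  # t/2 - l
        assert membrane_switch(20.5, m) == 1.0  # t/2 + l
        mid = membrane_switch(18.0, m)
        assert 0 < mid < 1


class TestGBEnergy:
    def test_born_ion_analytic(self, born_ion):
        radii = effective_born_radii(born_ion, AQUEOUS)
        e = gb_solvation_energy(born_ion, radii, eps_in=1.0, eps_out=80.0)
        assert e == pytest.approx(BORN_ANALYTIC, rel=1e-3)

    def test_zero_charges_zero_with_warning(self, born_ion):
        s = born_ion.copy()
        s.charges[:] = 0.0
        radii = effective_born_radii(s, AQUEOUS)
        with pytest.warns(UserWarning):
            assert gb_solvation_energy(s, radii) == 0.0

    def test_distant_ions_additive(self):
        s = make_born_system(charges=(1.0, 1.0), radius=2.0, separation=5000.0)
        radii = effective_born_radii(s, AQUEOUS)
        e = gb_solvation_energy(s, radii, eps_in=1.0, eps_out=80.0)
        assert e == pytest.approx(2 * BORN_ANALYTIC, rel=1e-3)

    def test_charge_mask_bilinearity(self, rng):
        """G(A u B) = G(A) + G(B) + cross(A, B) exactly at fixed radii."""
        coords = rng.uniform(-4, 4, (8, 3))
        s = charged_beads(coords, rng.uniform(-1, 1, 8))
        radii = effective_born_radii(s, AQUEOUS)
        a = np.arange(0, 4)
        b = np.arange(4, 8)
        g_ab = gb_solvation_energy(s, radii, charge_mask=np.arange(8))
        g_a = gb_solvation_energy(s, radii, charge_mask=a)
        g_b = gb_solvation_energy(s, radii, charge_mask=b)
        from posesieve.binding import _gb_cross_term

        m = MembraneModel()
        cross = _gb_cross_term(s, radii.radii, a, b, m.eps_mm_interior, m.eps_water)
        assert g_ab == pytest.approx(g_a + g_b + cross, abs=1e-9)

    def test_membrane_burial_monotone(self):
        m = MembraneModel()
        zs = [0.0, 14.0, 16.5, 18.0, 19.5, 23.0]
        mags = []
        for z in zs:
            ion = make_born_system(charges=(1.0,), radius=2.0, z_center=z)
            radii = effective_born_radii(ion, m)
            mags.append(abs(gb_solvation_energy(ion, radii, m)))
        assert mags == sorted(mags)


class TestPBSolver:
    GRID = GridSpec(n_points=(65, 65, 65), spacing=0.5)

    def test_born_ion_within_5_percent(self, born_ion):
        e = pb_solvation_energy(born_ion, self.GRID, mode="aqueous", eps_in=1.0)
        assert abs(e - BORN_ANALYTIC) / abs(BORN_ANALYTIC) < 0.05

    def test_refinement_reduces_error(self, born_ion):
        coarse = pb_solvation_energy(born_ion, self.GRID, mode="aqueous", eps_in=1.0)
        fine = pb_solvation_energy(
            born_ion, GridSpec(n_points=(65, 65, 65), spacing=0.25), mode="aqueous", eps_in=1.0
        )
        assert abs(fine - BORN_ANALYTIC) < abs(coarse - BORN_ANALYTIC)

    def test_no_dielectric_contrast_gives_zero(self, born_ion):
        m = MembraneModel(eps_water=1.0, eps_protein=1.0)
        e = pb_solvation_energy(born_ion, self.GRID, m, mode="aqueous", eps_in=1.0)
        assert abs(e) < 0.5  # numerical noise only

    def test_slab_desolvation_bound(self, born_ion):
        m = MembraneModel(eps_protein=1.0)
        slab = pb_solvation_energy(born_ion, self.GRID, m, mode="membrane", eps_in=1.0)
        aq = pb_solvation_energy(born_ion, self.GRID, m, mode="aqueous", eps_in=1.0)
        assert abs(slab) < 0.15 * abs(aq)

    def test_solute_outside_grid_rejected(self, born_ion):
        far = born_ion.with_coords(born_ion.coords + 100.0)
        with pytest.raises(ValueError):
            pb_solvation_energy(far, self.GRID, mode="aqueous")

    def test_gb_pb_correlation_slope(self, rng):
        """On random two-ion aqueous systems, GB and PB solvation agree to
        a regression slope within [0.8, 1.2]."""
        gbs, pbs = [], []
        for _ in range(10):
            q1, q2 = rng.choice([-1.0, 1.0], 2)
            sep = rng.uniform(4.5, 8.0)
            s = make_born_system(charges=(q1, q2), radius=2.0, separation=float(sep))
            radii = effective_born_radii(s, AQUEOUS)
            gbs.append(gb_solvation_energy(s, radii, eps_in=1.0, eps_out=80.0))
            pbs.append(pb_solvation_energy(s, self.GRID, mode="aqueous", eps_in=1.0, tol=1e-6))
        slope = np.polyfit(gbs, pbs, 1)[0]
        assert 0.8 < slope < 1.2


class TestMinimizer:
    def test_lj_pair_relaxes_to_minimum(self):
        s = charged_beads([[0, 0, 0], [0.9 * 3.8, 0, 0]], [0, 0])
        out, history = steepest_descent_minimize(s, n_steps=200, return_trajectory=True)
        r = np.linalg.norm(out.coords[1] - out.coords[0])
        assert r == pytest.approx(3.8, abs=0.01)
        assert history[-1] == pytest.approx(-0.12, abs=1e-4)

    def test_already_minimal_unchanged(self):
        s = charged_beads([[0, 0, 0], [3.8, 0, 0]], [0, 0])
        out = steepest_descent_minimize(s, n_steps=50)
        assert np.allclose(out.coords, s.coords, atol=0.02)

    def test_energy_monotone_on_random_fixture(self, rng):
        coords = rng.uniform(-6, 6, (20, 3))
        s = charged_beads(coords, rng.uniform(-0.3, 0.3, 20))
        _, history = steepest_descent_minimize(s, n_steps=100, return_trajectory=True)
        diffs = np.diff(history)
        assert np.all(diffs <= 1e-12)

    def test_fixed_atoms_do_not_move(self, rng):
        coords = rng.uniform(-5, 5, (10, 3))
        s = charged_beads(coords, np.zeros(10))
        out = steepest_descent_minimize(s, n_steps=50, fixed=np.arange(5))
        assert np.array_equal(out.coords[:5], coords[:5])
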