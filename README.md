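# posesieve

Post-docking assessment of membrane receptor–ligand structural models.

When a flexible peptide ligand is docked against an ensemble of receptor
conformations, the docking stage can produce hundreds of thousands of
candidate complexes that must be reduced to a handful of physically
plausible binding modes. `posesieve` implements the assessment side of
that workflow for receptors embedded in a membrane (e.g. GPCRs and their
peptide antagonists):

* **Cavity-shape fingerprints** — each receptor snapshot's binding pocket
  is encoded as a binary vector over a fixed grid of water-sized points
  (a bit is set when the point clears every receptor heavy atom by an
  exclusion radius, default 2.4 Å, and lies within 4 Å of a pocket-mouth
  region). Snapshots are compared with the Jaccard binary distance

  $$J_{AB} = \frac{C_{10} + C_{01}}{C_{10} + C_{01} + C_{11}}$$

  (0 = identical cavity occupation, 1 = disjoint), clustered
  hierarchically with a dendrogram cut at 0.3, and each family is
  represented by its largest-volume member.
* **Conformer and binding-mode clustering** — fixed-radius leader
  clustering of ligand side-chain torsions (45° radius, maximum
  per-angle circular difference metric) and of docked-pose mainchain
  coordinates (N/CA/C RMSD, 5 Å radius).
* **Steric pose filter** — a receptor–ligand atom pair clashes when the
  spheres overlap by more than 50 % of the sum of their radii
  (d < 0.5 (rᵢ + rⱼ)); poses with more than five clashes are rejected.
* **Implicit-membrane MM-GBSA / MM-PBSA scoring** — rigid end-point
  binding free energies ΔG = G_PL − G_P − G_L with intermolecular
  Coulomb and Lennard-Jones terms, a slab-membrane generalized-Born
  model (T_memb = 36 Å, l_msw = 2.5 Å), a finite-difference Poisson
  solver on a dielectric map (ε = 2 protein / 1 membrane slab of 31 Å /
  80 water; 150 grid points, 0.5 Å spacing), and a γ·SASA nonpolar term
  (γ = 0.04 kcal mol⁻¹ Å⁻²). The free ligand is solvated in water.
* **The sieve** — clash filter → steepest-descent minimization (ε = 4)
  → MM-GBSA → 27 kcal/mol energy window above the minimum → MM-PBSA
  rescore → mode clustering → lowest-energy representative per mode.
* **Residue-pair decomposition and maps** — per residue-pair polar
  (Coulomb + GB cross-term) and nonpolar (vdW + σΔSASA) interaction
  free energies, plus contact (6.5 Å moiety-center) and hydrogen-bond
  (3.5 Å, D–H⋯A > 90°) occupancy maps over trajectories.

A deterministic fixtures module generates synthetic receptors, cyclic
ligands, planted pose sets and analytic Born systems, so the whole
pipeline is testable without any external data.

## Worked example

```python
import numpy as np
from posesieve import *
from posesieve.fixtures import *

# 1. Energetics sanity: a +1 e ion of radius 2 Å, transferred from
#    vacuum (eps 1) into water (eps 80)
ion = make_born_system(charges=(1.0,), radius=2.0)
gb = gb_solvation_energy(ion, effective_born_radii(ion), eps_in=1.0, eps_out=80.0)
pb = pb_solvation_energy(ion, GridSpec(n_points=(65, 65, 65), spacing=0.5),
                         mode="aqueous", eps_in=1.0)
print(f"GB {gb:.3f}  PB {pb:.3f}  analytic {-0.5*COULOMB_K*(1-1/80)/2:.3f}")

# 2. Sieve a small planted pose set (two modes + one clashing pose)
receptor = make_toy_receptor(seed=0, n_rods=5, z_extent=9.0, rise=3.0)
ligand = make_cyclic_ligand()
poses = make_pose_set(seed=7, receptor=receptor, ligand=ligand,
                      n_modes=2, poses_per_mode=3, clash_counts=[8])
sieved = sieve_poses({"receptor": receptor}, poses, minimize_steps=5, run_pbsa=False)
print(sieved.stage_counts)
```

prints

```
GB -81.980  PB -85.861  analytic -81.980
{'input': 7, 'after_clash_filter': 6, 'after_minimization': 6,
 'after_window_filter': 6, 'after_pbsa': 6, 'modes': 2, 'representatives': 2}
```

The GB energy reproduces the analytic Born value exactly (a single ion
has no descreening), the finite-difference PB value carries the ~5 %
discretization error of a 0.5 Å grid, and the sieve removes exactly the
engineered 8-clash pose before recovering the two planted binding modes.

A command-line interface wraps the same machinery:

```sh
posesieve fixtures --kind pose_set --seed 7 --out fixtures/
posesieve filter-poses --receptor rec.pdb --poses poses.pdb \
    --params parameters.txt --max-clashes 5 --out clashes.tsv
posesieve sieve-run --config run.yaml
```

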