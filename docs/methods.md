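# Methods

This note documents the models implemented in `posesieve`, the
assumptions behind them, the defaults that matter, and what the
synthetic test systems do and do not establish.

## Coordinate and parameter conventions

The z-axis is the membrane normal and z = 0 the membrane center; every
membrane-dependent term reads only z. Residue numbering is taken
verbatim from input PDB files and never renumbered, so author numbering
survives into reports. Per-atom energetics parameters (partial charge,
Lennard-Jones ε and r_min/2, solvation radius) come from a plain-text
table keyed by (residue name, atom name); unmatched atoms are a hard
error in energetics contexts and a warning in pure geometry, because
nonstandard residues are expected to need user-supplied rows. The
mainchain atom set defaults to {N, CA, C, O} and is configurable so
N-terminal blocking groups can be treated as mainchain. Alternate
locations other than 'A'/blank are dropped with a warning. The
electrostatic constant is fixed at k = 332.0716 kcal·Å/(mol·e²) for
bit-reproducibility.

## Cavity fingerprints

The binding pocket of a superposed receptor snapshot is encoded on a
fixed regular lattice rather than an equilibrated water-box
configuration: the lattice gives a deterministic, portable catalogue of
identical resolution, with default spacing 2.8 Å (≈ one water diameter)
and a default 50 × 50 × 60 Å³ box whose origin is explicit in the
configuration. A point is present when (a) it clears every receptor
heavy atom by the exclusion radius (default 2.4 Å) and (b) it lies
within the inclusion radius (default 4 Å) of a user-supplied coordinate
set marking the pocket mouth — generalized from any particular ligand
to an arbitrary "inclusion region". Fingerprints are compared with the
Jaccard binary distance and clustered with scipy's agglomerative
linkage on the distance matrix, cut at 0.3. The linkage criterion is
average by default (standard for binary fingerprints), with single and
complete available for sensitivity checks; with single linkage, and
only then, frames in different clusters at cut c are guaranteed to be
more than c apart. A pair of all-zero fingerprints is defined to have
distance 0 (identical, if empty, cavities) but warns, since it usually
means a misplaced box. Each cluster is represented by its
largest-volume member; ties go to the earlier frame. A stride-based
subsampling mode is provided for trajectories whose cavity volume is
externally restrained and needs no shape clustering.

## Torsion and binding-mode clustering

Ligand conformers are clustered in circular angle space with a
two-phase fixed-radius algorithm: a leader pass in input order (assign
to the first center within the radius, else seed a new cluster)
followed by refinement passes that recompute centers as per-angle
circular means and reassign to the nearest center until a fixpoint.
The metric is the **maximum** per-angle circular difference, so the
45° default radius bounds every dihedral individually; an RMS-of-angles
metric is available. The 10° "maximum error" radius is a diagnostic: it
triggers a warning when the final refinement pass moved any center
further, never a failure. Leader clustering is order-dependent by
construction; identical input order gives identical output, and callers
can pre-sort by energy for reproducibility across shuffles.

Binding modes are leader clusters of ligand mainchain (N, CA, C)
coordinates at a 5 Å RMSD radius, computed **without** re-superposition
because docked poses share the receptor frame by construction (a config
flag enables pre-superposition for foreign inputs). Each mode is
represented by its lowest-energy member; ties go to the lower pose
index.

## Clash filter

"Overlap greater than half the combined radii" is implemented as
d < (1 − f)(rᵢ + rⱼ) with f = 0.5, i.e. the overlap depth
rᵢ + rⱼ − d exceeds f of the radius sum; f is configurable so the
alternative reading can be emulated. The inequality is strict: a pair
exactly at the threshold is not a clash. Radii are the solvation-radius
column (one radius set shared with energetics); hydrogens are excluded.
The KD-tree neighbour search prefilters at the largest possible
threshold and then applies the exact per-pair test, so its counts equal
the all-pairs loop by construction (and are tested to).

## Implicit-membrane generalized Born

Polar solvation uses Hawkins–Cramer–Truhlar pairwise descreening:
each atom's inverse Born radius is its inverse intrinsic radius minus
the closed-form integral of 1/s⁴ over every neighbour sphere. The
membrane enters through a switching function S(z) — 0 for
|z| ≤ T_memb/2 − l_msw, 1 beyond T_memb/2 + l_msw, a smooth cubic in
the interface — which rescales the inverse Born radius, so fully buried
atoms approach a desolvated limit (radii capped at 10⁴ Å to stay
finite). Defaults: T_memb = 36 Å, l_msw = 2.5 Å. The GB energy is the
canonical form with f_GB = √(r² + αᵢαⱼ exp(−r²/4αᵢαⱼ)), interior
dielectric 1 (matching the MM terms) and solvent dielectric 80.
This slab GB is the package's central approximation: it keeps the
standard membrane slab parameters but is a documented
pairwise-descreening model, not a reimplementation of any MD package's membrane GB. Its role
is a qualitatively faithful, fully testable sieve stage; the Born-ion
and two-atom descreening oracles, the bilinearity identity and the
burial-monotonicity property pin down its behaviour.

## Finite-difference Poisson solver

The PB stage solves the linearized, zero-ionic-strength Poisson
equation on a regular grid (defaults 150 points per axis, 0.5 Å
spacing). The dielectric map is evaluated at face centers: ε_protein
(default 2) inside any atom sphere, ε_membrane (default 1) in the slab
|z| ≤ 31/2 Å outside the solute, ε_water (80) elsewhere; the solute
interior is a sharp atom-sphere union with no molecular-surface
smoothing (a deliberate simplification; a smoothing hook exists in the
map function). Charges are spread trilinearly; boundary potentials are
Coulombic with the solvent dielectric. The solvation energy is the
difference between the map solve and a uniform-ε_protein reference
solve on the identical grid, which cancels the spread-charge self
energy. The symmetric positive-definite 7-point system is solved by
conjugate gradients preconditioned with the exact inverse of the
unit-coefficient Dirichlet Laplacian (3-D discrete sine transforms);
the uniform reference solve uses the DST solve directly. Convergence is
a relative residual below 10⁻⁶ (configurable); non-convergence is an
error. On the Born ion the discretization error is ≈ 4 % at 0.5 Å and
≈ 1 % at 0.25 Å.

In binding contexts all three states (complex, receptor, ligand) share
one grid geometry — the receptor context simply drops the ligand's
charges and dielectric spheres, and vice versa — so per-atom spread
self-energies cancel in ΔG. The free ligand's map has no membrane slab
(pure water).

## Binding free energies and the sieve

ΔG = G_PL − G_P − G_L in the rigid single-geometry approximation:
receptor and ligand conformations are identical bound and free, so
bonded and intramolecular nonbonded terms cancel and only
intermolecular Coulomb (ε = 1) and Lennard-Jones (CHARMM-style
combination rules, no cutoff when rescoring; a 16 Å cutoff is
available), the solvation difference, and γ·ΔSASA remain.
Configurational entropy is omitted throughout. Complex and free
receptor are solvated in the membrane environment, the free ligand in
water. The same γΔSASA term is applied in both the GBSA and PBSA
scores (configurable off). SASA is Shrake–Rupley quadrature
(deterministic Fibonacci point set, 960 points, 1.4 Å probe) over heavy
atoms with the shared radius set.

The sieve runs: clash filter → steepest-descent minimization (100
steps, uniform ε = 4, ligand mobile against a fixed receptor) →
MM-GBSA → energy window (keep poses within 27 kcal/mol of the minimum,
boundary inclusive) → MM-PBSA rescore → 5 Å mainchain mode clustering →
lowest-PBSA representative per mode. A short implicit-solvent
minimization between the uniform-dielectric relaxation and rescoring
was considered and omitted: analytic GB gradients are out of scope, so
the uniform-dielectric geometry is rescored directly. The minimizer is adaptive steepest
descent (step halved on energy increase, grown 1.2× on acceptance), so
accepted-step energies are non-increasing by construction;
near-singular contacts reject the step, and only persistent
non-finite behaviour raises.

## Residue-pair decomposition

For receptor residue R and ligand residue R′:
polar = Σ Coulomb(i∈R, j∈R′) + GB cross-term; nonpolar = Σ LJ + σΔSASA.
Born radii are computed **once** from the full complex and frozen for
every charge-masked evaluation; under fixed radii the GB energy is a
quadratic form in the charges, so the cross term (equivalently the
three-mask difference G(R∪R′) − G(R) − G(R′)) is exact and the table
sums reproduce the complex's total intermolecular polar energy to
numerical precision — a tested conservation law. The surface term is
each residue's ΔSASA (complex minus unbound context) times γ,
attributed once: by default to the residue's highest-|vdW| partner
pair, optionally split evenly; either policy conserves the table total,
and neither is claimed to be canonical because the attribution among
multiple partners is genuinely underdetermined. Reports default to a
1.8 kcal/mol magnitude threshold.

## Contact and hydrogen-bond maps

Contacts: four maps over the moiety pairings (side chain/mainchain ×
receptor/ligand), heavy atoms only; a contact exists in a frame when
the moiety geometric centers are closer than 6.5 Å (strict). Residues
with an empty moiety (glycine-like side chains) are flagged undefined
and reported as absent. Hydrogen bonds: donor–acceptor heavy-atom
distance < 3.5 Å AND some donor hydrogen with D–H⋯A angle > 90°; when
the topology carries no hydrogens the angle gate falls back to the
antecedent–D–A pseudo-angle and the pair is flagged. Occupancies are
percentages of frames, reported to 0.1 %.

## Synthetic test systems

The fixtures module emulates the geometric and energetic structure the
framework assumes, not the chemistry of any real receptor: a toy
membrane receptor (5–7 pseudo-helical bead rods spanning |z| ≤ 18 Å
around a 6 Å pore), a cyclic six-residue bead ligand with nine defined
side-chain dihedrals, pose sets with translation-planted binding modes
(separation 12 Å > 2× the mode radius, jitter 0.5 Å < radius/3) and
poses engineered to carry an exact clash count, pocket ensembles with
two planted cavity families, and one/two-ion Born systems with
closed-form solvation. All generators are pure functions of their
arguments; bead chemistry is one LJ type with ±0.1–0.2 e charges.
Planted-structure parameters are chosen so the recovery oracles are
decisive. Passing these tests establishes the algorithms' contracts —
filter boundaries, conservation laws, metric properties, recovery of
well-separated structure, determinism — but says nothing about
force-field accuracy on real proteins, about cavities whose families
overlap near the dendrogram cut, or about docking poses whose modes are
closer than the clustering radius.

## Problem sizes and defaults in the shipped tests

The test suite exercises the PB solver at its 150³/0.5 Å defaults for
the Born-ion oracle and at 49³–65³ grids elsewhere; sieve and pipeline
tests use a reduced receptor (5 rods, ~140 atoms) with shortened
minimizations, sizes chosen so the planted structure remains decisively
recoverable. The end-to-end fixture pipeline (cavity clustering,
torsion clustering, clash/GBSA/window/PBSA sieve, decomposition and
maps) runs twice and must produce byte-identical outputs; no output
carries a timestamp.

## Known limitations

* The slab GB is not GBSW/GBMV; membrane energetics are qualitative.
* The PB dielectric boundary is a sharp sphere union; no molecular
  surface, no ionic strength, no focusing.
* The minimizer covers Coulomb + LJ only (bond terms are expected to be
  handled upstream or frozen); single-structure minimization needs a
  user-supplied exclusion list for bonded pairs.
* Pose provenance in the pipeline assigns all externally supplied poses
  to one representative receptor frame per run.
* Leader clustering partitions depend on input order, as documented.
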