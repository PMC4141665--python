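"""Core structural types and geometry.

Defines the atom/structure containers used throughout the package, PDB
reading and writing, an atom-selection mini-language, least-squares rigid
superposition, RMSD, dihedral angles and geometric centers.

Conventions
-----------
* Coordinates are in Angstrom. The z-axis is the membrane normal and
  z = 0 is the membrane center; all membrane-dependent energy terms read
  only z.
* Residue numbering is taken verbatim from the input PDB (author
  numbering) and never renumbered.
* The mainchain atom set defaults to {N, CA, C, O} and is configurable so
  that blocking-group atoms (e.g. acetyl caps) can be treated as
  mainchain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "AtomRecord",
    "MolecularStructure",
    "ConformationEnsemble",
    "AtomSelection",
    "ParameterTable",
    "PDBFormatError",
    "SelectionError",
    "ParameterError",
    "DEFAULT_MAINCHAIN_NAMES",
    "read_structure",
    "write_structure",
    "select_atoms",
    "superpose",
    "rmsd",
    "dihedral_angle",
    "geometric_center",
    "read_parameter_table",
    "write_parameter_table",
    "apply_parameters",
]

#: Atom names treated as mainchain by default. Extend (e.g. with acetyl
#: cap atoms "CAY", "CY", "OY") via the ``mainchain_names`` argument of
#: :class:`MolecularStructure`.
DEFAULT_MAINCHAIN_NAMES = frozenset({"N", "CA", "C", "O"})

_HYDROGEN_ELEMENTS = frozenset({"H", "D"})


class PDBFormatError(ValueError):
    """Raised for unparsable PDB content; messages name the line number."""


class SelectionError(ValueError):
    """Raised for malformed selection expressions; names the token position."""


class ParameterError(KeyError):
    """Raised when per-atom parameters are missing for an energetics call."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AtomRecord:
    """A single atom with geometry and (optional) energetics parameters.

    ``charge`` is in elementary charges, ``lj_epsilon`` in kcal/mol,
    ``lj_rmin_half`` and ``solvation_radius`` in Angstrom. Parameters are
    NaN until a :class:`ParameterTable` is applied.
    """

    serial: int
    name: str
    element: str
    residue_name: str
    residue_id: int
    chain_id: str
    position: np.ndarray
    charge: float = float("nan")
    lj_epsilon: float = float("nan")
    lj_rmin_half: float = float("nan")
    solvation_radius: float = float("nan")
    is_mainchain: bool = False


class MolecularStructure:
    """Ordered atom collection with residue bookkeeping.

    Internally column-oriented (numpy arrays) for vectorised energetics;
    :attr:`atoms` materialises :class:`AtomRecord` rows on demand. Atoms of
    one (chain, residue) pair must be contiguous.
    """

    def __init__(
        self,
        names: Sequence[str],
        elements: Sequence[str],
        residue_names: Sequence[str],
        residue_ids: Sequence[int],
        chain_ids: Sequence[str],
        coords: np.ndarray,
        serials: Sequence[int] | None = None,
        charges: np.ndarray | None = None,
        lj_epsilon: np.ndarray | None = None,
        lj_rmin_half: np.ndarray | None = None,
        solvation_radius: np.ndarray | None = None,
        frame_label: str = "",
        mainchain_names: Iterable[str] | None = None,
    ):
        n = len(names)
        self.names = np.asarray(names, dtype=object)
        self.elements = np.asarray([e.upper() for e in elements], dtype=object)
        self.residue_names = np.asarray(residue_names, dtype=object)
        self.residue_ids = np.asarray(residue_ids, dtype=int)
        self.chain_ids = np.asarray(chain_ids, dtype=object)
        self.coords = np.array(coords, dtype=float).reshape(n, 3)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        self.serials = (
            np.asarray(serials, dtype=int)
            if serials is not None
            else np.arange(1, n + 1)
        )
        nan = np.full(n, np.nan)
        self.charges = np.array(charges, dtype=float) if charges is not None else nan.copy()
        self.lj_epsilon = np.array(lj_epsilon, dtype=float) if lj_epsilon is not None else nan.copy()
        self.lj_rmin_half = np.array(lj_rmin_half, dtype=float) if lj_rmin_half is not None else nan.copy()
        self.solvation_radius = (
            np.array(solvation_radius, dtype=float) if solvation_radius is not None else nan.copy()
        )
        self.frame_label = frame_label
        self.mainchain_names = frozenset(mainchain_names) if mainchain_names is not None else DEFAULT_MAINCHAIN_NAMES
        self._build_residue_index()

    # -- bookkeeping --------------------------------------------------------

    def _build_residue_index(self) -> None:
        index: dict[tuple[str, int], slice] = {}
        n = self.n_atoms
        start = 0
        for i in range(1, n + 1):
            if i == n or (
                self.chain_ids[i] != self.chain_ids[start]
                or self.residue_ids[i] != self.residue_ids[start]
            ):
                key = (str(self.chain_ids[start]), int(self.residue_ids[start]))
                if key in index:
                    raise ValueError(
                        f"atoms of residue {key} are not contiguous in the atom list"
                    )
                index[key] = slice(start, i)
                start = i
        self.residue_index: dict[tuple[str, int], slice] = index

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def is_mainchain(self) -> np.ndarray:
        return np.array([n in self.mainchain_names for n in self.names], dtype=bool)

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.array([e not in _HYDROGEN_ELEMENTS for e in self.elements], dtype=bool)

    @property
    def atoms(self) -> list[AtomRecord]:
        mc = self.is_mainchain
        return [
            AtomRecord(
                serial=int(self.serials[i]),
                name=str(self.names[i]),
                element=str(self.elements[i]),
                residue_name=str(self.residue_names[i]),
                residue_id=int(self.residue_ids[i]),
                chain_id=str(self.chain_ids[i]),
                position=self.coords[i].copy(),
                charge=float(self.charges[i]),
                lj_epsilon=float(self.lj_epsilon[i]),
                lj_rmin_half=float(self.lj_rmin_half[i]),
                solvation_radius=float(self.solvation_radius[i]),
                is_mainchain=bool(mc[i]),
            )
            for i in range(self.n_atoms)
        ]

    def residues(self) -> list[tuple[str, int]]:
        return list(self.residue_index)

    # -- derived structures -------------------------------------------------

    def copy(self) -> "MolecularStructure":
        return self.subset(np.arange(self.n_atoms))

    def subset(self, indices: np.ndarray | Sequence[int], frame_label: str | None = None) -> "MolecularStructure":
        idx = np.asarray(indices, dtype=int)
        return MolecularStructure(
            names=self.names[idx],
            elements=self.elements[idx],
            residue_names=self.residue_names[idx],
            residue_ids=self.residue_ids[idx],
            chain_ids=self.chain_ids[idx],
            coords=self.coords[idx],
            serials=self.serials[idx],
            charges=self.charges[idx],
            lj_epsilon=self.lj_epsilon[idx],
            lj_rmin_half=self.lj_rmin_half[idx],
            solvation_radius=self.solvation_radius[idx],
            frame_label=self.frame_label if frame_label is None else frame_label,
            mainchain_names=self.mainchain_names,
        )

    def with_coords(self, coords: np.ndarray, frame_label: str | None = None) -> "MolecularStructure":
        out = self.copy()
        out.coords = np.array(coords, dtype=float).reshape(self.n_atoms, 3)
        if frame_label is not None:
            out.frame_label = frame_label
        return out

    def select(self, expression: str) -> "AtomSelection":
        return select_atoms(self, expression)


@dataclass
class ConformationEnsemble:
    """A topology shared by multiple coordinate frames (e.g. MD snapshots)."""

    topology: MolecularStructure
    frames: np.ndarray  # (n_frames, n_atoms, 3)
    frame_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.frames = np.array(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1:] != (self.topology.n_atoms, 3):
            raise ValueError(
                f"frames shape {self.frames.shape} incompatible with "
                f"{self.topology.n_atoms}-atom topology"
            )
        if not self.frame_labels:
            self.frame_labels = [f"frame{i}" for i in range(len(self.frames))]
        if len(self.frame_labels) != len(self.frames):
            raise ValueError("frame_labels length mismatch")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def structure(self, i: int) -> MolecularStructure:
        return self.topology.with_coords(self.frames[i], frame_label=self.frame_labels[i])

    def __iter__(self):
        return (self.structure(i) for i in range(self.n_frames))


@dataclass(frozen=True)
class AtomSelection:
    """A resolved atom selection: the source expression plus sorted indices."""

    expression: str
    indices: np.ndarray

    def __post_init__(self):
        idx = np.asarray(self.indices, dtype=int)
        if idx.size and (np.any(np.diff(idx) <= 0) or idx[0] < 0):
            raise ValueError("selection indices must be unique and ascending")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)


# ---------------------------------------------------------------------------
# PDB I/O (thin wrappers over biotite with stricter validation)
# ---------------------------------------------------------------------------

def _validate_pdb_lines(lines: Sequence[str]) -> None:
    """Pre-validate ATOM/HETATM coordinate fields, naming bad line numbers."""
    saw_altloc = False
    for lineno, line in enumerate(lines, start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        if len(line.rstrip("\n")) < 54:
            raise PDBFormatError(f"line {lineno}: truncated ATOM/HETATM record")
        try:
            float(line[30:38])
            float(line[38:46])
            float(line[46:54])
            int(line[22:26])
        except ValueError as exc:
            raise PDBFormatError(f"line {lineno}: unparsable field ({exc})") from None
        if line[16] not in (" ", "A"):
            saw_altloc = True
    if saw_altloc:
        warnings.warn(
            "alternate locations other than 'A'/blank present; keeping altloc 'A'",
            stacklevel=3,
        )


def _structure_from_atom_array(arr, frame_label: str) -> MolecularStructure:
    elements = [e if e else n[0] for e, n in zip(arr.element, arr.atom_name)]
    return MolecularStructure(
        names=list(arr.atom_name),
        elements=elements,
        residue_names=list(arr.res_name),
        residue_ids=list(arr.res_id),
        chain_ids=[c if c.strip() else "A" for c in arr.chain_id],
        coords=np.asarray(arr.coord, dtype=float),
        frame_label=frame_label,
    )


def read_structure(path: str | Path, model_policy: str = "first"):
    """Read a PDB file.

    Parameters
    ----------
    path:
        PDB file path.
    model_policy:
        ``"first"`` returns a :class:`MolecularStructure` from the first
        MODEL; ``"all"`` returns a :class:`ConformationEnsemble` with one
        frame per MODEL block.
    """
    from biotite.structure.io.pdb import PDBFile

    path = Path(path)
    text = path.read_text()
    _validate_pdb_lines(text.splitlines())

    pdb = PDBFile.read(str(path))
    if model_policy not in ("first", "all"):
        raise ValueError(f"unknown model_policy {model_policy!r}")
    label = path.stem
    if model_policy == "first":
        arr = pdb.get_structure(model=1, altloc="first")
        if arr.array_length() == 0:
            raise PDBFormatError(f"{path}: no atoms")
        return _structure_from_atom_array(arr, label)
    stack = pdb.get_structure(altloc="first")
    if stack.array_length() == 0:
        raise PDBFormatError(f"{path}: no atoms")
    topo = _structure_from_atom_array(stack[0], label)
    labels = [f"{label}:{i + 1}" for i in range(stack.stack_depth())]
    return ConformationEnsemble(topo, np.asarray(stack.coord, dtype=float), labels)


def _to_atom_array(s: MolecularStructure):
    import biotite.structure as struc

    arr = struc.AtomArray(s.n_atoms)
    arr.coord = s.coords.astype(np.float32)
    arr.atom_name = s.names.astype("U6")
    arr.element = s.elements.astype("U2")
    arr.res_name = s.residue_names.astype("U5")
    arr.res_id = s.residue_ids
    arr.chain_id = s.chain_ids.astype("U4")
    arr.hetero = np.zeros(s.n_atoms, dtype=bool)
    return arr


def write_structure(s, path: str | Path) -> None:
    """Write a structure or ensemble as PDB (MODEL blocks for ensembles)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    if isinstance(s, ConformationEnsemble):
        if s.topology.n_atoms == 0:
            raise ValueError("cannot write empty structure")
        coords = s.frames
        base = s.topology
    else:
        if s.n_atoms == 0:
            raise ValueError("cannot write empty structure")
        coords = s.coords[None]
        base = s
    if np.any(np.abs(coords) >= 1e4):
        raise OverflowError("coordinate magnitude >= 1e4 A does not fit PDB columns")
    arr = _to_atom_array(base)
    pdb = PDBFile()
    if coords.shape[0] == 1:
        arr.coord = coords[0].astype(np.float32)
        pdb.set_structure(arr)
    else:
        stack = struc.stack([arr] * coords.shape[0])
        stack.coord = coords.astype(np.float32)
        pdb.set_structure(stack)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Atom selection mini-language
# ---------------------------------------------------------------------------
#
# Grammar (tokens whitespace-separated; lists comma-separated, no spaces):
#   expr    := or
#   or      := and ("or" and)*
#   and     := unary ("and" unary)*
#   unary   := "not" unary | "(" expr ")" | primary
#   primary := "all" | "none" | "mainchain" | "sidechain" | "heavy"
#            | "hydrogen" | "name" LIST | "resname" LIST | "chain" LIST
#            | "resid" RANGELIST       (e.g. resid 3,7-12,40)

_KEYWORDS = {"all", "none", "mainchain", "sidechain", "heavy", "hydrogen"}
_FIELDS = {"name", "resname", "chain", "resid"}


class _SelParser:
    def __init__(self, s: MolecularStructure, expr: str):
        self.s = s
        self.tokens = expr.split()
        self.pos = 0
        if not self.tokens:
            raise SelectionError("empty selection expression")

    def _err(self, msg: str):
        raise SelectionError(f"token {self.pos + 1}: {msg}")

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self):
        tok = self.peek()
        if tok is None:
            self._err("unexpected end of expression")
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.parse_or()
        if self.peek() is not None:
            self._err(f"unexpected token {self.peek()!r}")
        return mask

    def parse_or(self):
        mask = self.parse_and()
        while self.peek() == "or":
            self.take()
            mask = mask | self.parse_and()
        return mask

    def parse_and(self):
        mask = self.parse_unary()
        while self.peek() == "and":
            self.take()
            mask = mask & self.parse_unary()
        return mask

    def parse_unary(self):
        tok = self.peek()
        if tok == "not":
            self.take()
            return ~self.parse_unary()
        if tok == "(":
            self.take()
            mask = self.parse_or()
            if self.peek() != ")":
                self._err("expected ')'")
            self.take()
            return mask
        return self.parse_primary()

    def parse_primary(self):
        s = self.s
        tok = self.take()
        if tok == "all":
            return np.ones(s.n_atoms, dtype=bool)
        if tok == "none":
            return np.zeros(s.n_atoms, dtype=bool)
        if tok == "mainchain":
            return s.is_mainchain
        if tok == "sidechain":
            return ~s.is_mainchain & s.heavy_mask
        if tok == "heavy":
            return s.heavy_mask
        if tok == "hydrogen":
            return ~s.heavy_mask
        if tok in _FIELDS:
            arg = self.take()
            items = arg.split(",")
            if tok == "name":
                return np.isin(s.names.astype(str), items)
            if tok == "resname":
                return np.isin(s.residue_names.astype(str), items)
            if tok == "chain":
                return np.isin(s.chain_ids.astype(str), items)
            # resid: integers and a-b ranges
            mask = np.zeros(s.n_atoms, dtype=bool)
            for item in items:
                try:
                    if "-" in item[1:]:  # allow leading minus
                        split_at = item.index("-", 1)
                        lo, hi = int(item[:split_at]), int(item[split_at + 1:])
                        mask |= (s.residue_ids >= lo) & (s.residue_ids <= hi)
                    else:
                        mask |= s.residue_ids == int(item)
                except ValueError:
                    self._err(f"bad resid item {item!r}")
            return mask
        self._err(f"unknown token {tok!r}")


def select_atoms(s: MolecularStructure, expression: str) -> AtomSelection:
    """Resolve a selection expression to an ordered :class:`AtomSelection`.

    An empty result is allowed but warned about.
    """
    mask = _SelParser(s, expression).parse()
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        warnings.warn(f"selection {expression!r} matched no atoms", stacklevel=2)
    return AtomSelection(expression=expression, indices=idx)


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def superpose(
    mobile: MolecularStructure,
    reference: MolecularStructure,
    mobile_sel: AtomSelection,
    reference_sel: AtomSelection,
) -> tuple[MolecularStructure, float]:
    """Least-squares rigid superposition (Kabsch).

    Fits the ``mobile_sel`` atoms of *mobile* onto the ``reference_sel``
    atoms of *reference*, applies the proper-rotation + translation to ALL
    mobile atoms, and returns the transformed structure with the RMSD over
    the fit atoms.
    """
    mi, ri = mobile_sel.indices, reference_sel.indices
    if len(mi) != len(ri):
        raise ValueError("superposition selections differ in length")
    if len(mi) < 3:
        raise ValueError("superposition needs at least 3 atom pairs")
    mob = mobile.coords[mi]
    ref = reference.coords[ri]
    mob_c, ref_c = mob.mean(axis=0), ref.mean(axis=0)
    a, b = ref - ref_c, mob - mob_c
    if np.linalg.matrix_rank(a, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) reference geometry")
    rot, rssd = Rotation.align_vectors(a, b)
    new_coords = (mobile.coords - mob_c) @ rot.as_matrix().T + ref_c
    fit_rmsd = float(rssd / np.sqrt(len(mi)))
    return mobile.with_coords(new_coords), fit_rmsd


def rmsd(a: np.ndarray, b: np.ndarray, selection: AtomSelection | None = None) -> float:
    """Root-mean-square deviation over a selection; no superposition."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if selection is not None:
        if len(selection) == 0:
            raise ValueError("empty selection in rmsd")
        a = a[selection.indices]
        b = b[selection.indices]
    if a.shape != b.shape or a.size == 0:
        raise ValueError("rmsd requires congruent, non-empty coordinate sets")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def dihedral_angle(coords: np.ndarray, atoms: Sequence[int]) -> float:
    """Dihedral (torsion) angle in degrees, in (-180, 180].

    IUPAC sign convention: cis (eclipsed) = 0. ``coords`` may be a
    structure's coordinate array; ``atoms`` are four distinct indices.
    """
    if hasattr(coords, "coords"):
        coords = coords.coords
    i, j, k, l = atoms
    if len({i, j, k, l}) != 4:
        raise ValueError("dihedral needs four distinct atoms")
    p = np.asarray(coords, dtype=float)
    b1 = p[j] - p[i]
    b2 = p[k] - p[j]
    b3 = p[l] - p[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise ValueError("undefined dihedral: collinear atoms about the central bond")
    b2hat = b2 / np.linalg.norm(b2)
    ang = float(np.degrees(np.arctan2(np.dot(np.cross(n1, n2), b2hat), np.dot(n1, n2))))
    if ang <= -180.0:
        ang += 360.0
    return ang


def geometric_center(coords: np.ndarray, selection: AtomSelection | None = None) -> np.ndarray:
    """Unweighted mean position of the selected atoms."""
    if hasattr(coords, "coords"):
        coords = coords.coords
    c = np.asarray(coords, dtype=float)
    if selection is not None:
        if len(selection) == 0:
            raise ValueError("empty selection in geometric_center")
        c = c[selection.indices]
    if c.size == 0:
        raise ValueError("geometric center of zero atoms")
    return c.mean(axis=0)


# ---------------------------------------------------------------------------
# Per-atom parameter table
# ---------------------------------------------------------------------------
# Plain-text format, whitespace separated, '#' comments:
#   RESNAME ATOMNAME CHARGE LJ_EPSILON LJ_RMIN_HALF RADIUS

class ParameterTable(dict):
    """(residue_name, atom_name) -> (charge, lj_epsilon, lj_rmin_half, radius)."""


def read_parameter_table(path: str | Path) -> ParameterTable:
    table = ParameterTable()
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 6:
            raise ValueError(f"parameter table line {lineno}: expected 6 columns")
        res, name = parts[0], parts[1]
        try:
            vals = tuple(float(x) for x in parts[2:])
        except ValueError:
            raise ValueError(f"parameter table line {lineno}: non-numeric value") from None
        table[(res, name)] = vals
    return table


def write_parameter_table(table: Mapping, path: str | Path) -> None:
    lines = ["# RESNAME ATOMNAME CHARGE LJ_EPSILON LJ_RMIN_HALF RADIUS"]
    for (res, name), (q, eps, rmh, rad) in table.items():
        lines.append(f"{res:<6s} {name:<6s} {q:10.5f} {eps:10.5f} {rmh:10.5f} {rad:10.5f}")
    Path(path).write_text("\n".join(lines) + "\n")


def apply_parameters(s: MolecularStructure, table: Mapping, strict: bool = True) -> MolecularStructure:
    """Assign charges/LJ/radii from a parameter table; returns a new structure.

    Lookup key is (residue_name, atom_name). Unmatched atoms are a hard
    error when ``strict`` (energetics contexts), a warning otherwise.
    """
    out = s.copy()
    missing = []
    for i in range(s.n_atoms):
        key = (str(s.residue_names[i]), str(s.names[i]))
        row = table.get(key)
        if row is None:
            missing.append(key)
            continue
        out.charges[i], out.lj_epsilon[i], out.lj_rmin_half[i], out.solvation_radius[i] = row
    if missing:
        msg = f"{len(missing)} atoms without parameters, e.g. {missing[:3]}"
        if strict:
            raise ParameterError(msg)
        warnings.warn(msg, stacklevel=2)
    return out
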