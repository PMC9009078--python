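"""Periodic structure model for molecular crystals.

A crystal is represented by its lattice cell, space-group symmetry
operations and an asymmetric unit of atoms in fractional coordinates.
Every atom generated from the asymmetric unit keeps a record of which
asymmetric-unit site produced it (``site_id``), through which symmetry
operation (``op_id``) and lattice translation (``cell_offset``).  That
identity is what lets per-site properties — point charges, hydrogen
displacements — be mapped onto every periodic image of a site.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from functools import cached_property
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist

__all__ = [
    "LatticeCell",
    "SymmetryOp",
    "Atom",
    "Molecule",
    "MolecularCrystal",
    "expand_symmetry",
    "build_supercell",
    "perceive_molecules",
    "read_cif",
    "write_xyz",
    "CrystalError",
    "ClashError",
]

#: default fractional inflation of the covalent-radius sum used for bonding
BOND_TOLERANCE = 0.25

#: two symmetry images whose atoms all coincide within this distance (Å)
#: are the same molecule on a special position
SPECIAL_POSITION_TOL = 1e-3

#: distinct molecules with an interatomic contact below this (Å) are a clash
CLASH_DISTANCE = 0.5


class CrystalError(ValueError):
    """Invalid crystal model or operation on one."""


class ClashError(CrystalError):
    """Two distinct molecules overlap."""


@dataclass(frozen=True)
class LatticeCell:
    """Unit-cell parameters: lengths in Å, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise CrystalError(f"cell lengths must be positive: {self}")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise CrystalError(f"cell angles must lie in (0, 180): {self}")
        if self.volume <= 0 or not math.isfinite(self.volume):
            raise CrystalError(f"degenerate cell (volume <= 0): {self}")

    @cached_property
    def matrix(self) -> np.ndarray:
        """Cell matrix with lattice vectors as columns; a ∥ x, b in the xy-plane."""
        al, be, ga = np.radians([self.alpha, self.beta, self.gamma])
        cx = self.c * np.cos(be)
        cy = self.c * (np.cos(al) - np.cos(be) * np.cos(ga)) / np.sin(ga)
        cz_sq = self.c**2 - cx**2 - cy**2
        if cz_sq <= 0:
            raise CrystalError(f"inconsistent cell angles: {self}")
        return np.array(
            [
                [self.a, self.b * np.cos(ga), cx],
                [0.0, self.b * np.sin(ga), cy],
                [0.0, 0.0, math.sqrt(cz_sq)],
            ]
        )

    @cached_property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)

    @property
    def volume(self) -> float:
        al, be, ga = np.radians([self.alpha, self.beta, self.gamma])
        cos = np.cos([al, be, ga])
        arg = 1.0 - np.dot(cos, cos) + 2.0 * cos.prod()
        if arg <= 0:
            return 0.0
        return float(self.a * self.b * self.c * math.sqrt(arg))

    def frac_to_cart(self, frac: np.ndarray) -> np.ndarray:
        """Fractional → Cartesian (Å); accepts a single vector or an (N, 3) array."""
        return np.asarray(frac, dtype=float) @ self.matrix.T

    def cart_to_frac(self, cart: np.ndarray) -> np.ndarray:
        return np.asarray(cart, dtype=float) @ self.inverse.T

    def perpendicular_widths(self) -> np.ndarray:
        """Distance between opposite cell faces along each axis (Å)."""
        m = self.matrix
        v = self.volume
        areas = [
            np.linalg.norm(np.cross(m[:, (i + 1) % 3], m[:, (i + 2) % 3]))
            for i in range(3)
        ]
        return v / np.asarray(areas)


@dataclass(frozen=True)
class SymmetryOp:
    """Space-group operation acting on fractional coordinates: x' = R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        rot = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        tr = np.mod(np.asarray(self.translation, dtype=float).reshape(3), 1.0)
        det = round(np.linalg.det(rot))
        if det not in (1, -1):
            raise CrystalError(f"symmetry rotation determinant {det} not ±1")
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", tr)

    @classmethod
    def from_xyz(cls, triplet: str) -> "SymmetryOp":
        """Parse an xyz-style operation string such as ``-x, y+1/2, -z``."""
        op = gemmi.Op(triplet)
        return cls(np.array(op.rot) / op.DEN, np.array(op.tran) / op.DEN)

    @classmethod
    def identity(cls) -> "SymmetryOp":
        return cls(np.eye(3), np.zeros(3))

    @property
    def is_identity(self) -> bool:
        return np.allclose(self.rotation, np.eye(3)) and np.allclose(
            self.translation, 0.0
        )

    def apply(self, frac: np.ndarray) -> np.ndarray:
        return np.asarray(frac, dtype=float) @ self.rotation.T + self.translation


@dataclass(frozen=True)
class Atom:
    """One atom, identified by its generating asymmetric-unit site.

    ``frac`` is the fractional position actually occupied (wrapping and
    lattice translation already applied); ``(site_id, op_id, cell_offset)``
    uniquely identifies the atom in any supercell.
    """

    element: str
    frac: tuple[float, float, float]
    site_id: int
    op_id: int = 0
    cell_offset: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        if covalent_radius(self.element) is None:
            raise CrystalError(f"unknown element symbol {self.element!r}")
        object.__setattr__(self, "frac", tuple(float(x) for x in self.frac))
        object.__setattr__(self, "cell_offset", tuple(int(x) for x in self.cell_offset))

    @property
    def key(self) -> tuple[int, int, tuple[int, int, int]]:
        return (self.site_id, self.op_id, self.cell_offset)

    def shifted(self, offset: Sequence[int]) -> "Atom":
        off = tuple(int(o) for o in offset)
        return replace(
            self,
            frac=tuple(np.asarray(self.frac) + off),
            cell_offset=tuple(np.asarray(self.cell_offset, dtype=int) + off),
        )


@dataclass(frozen=True)
class Molecule:
    """A bond-connected set of atoms with resolved Cartesian coordinates."""

    atoms: tuple[Atom, ...]
    cell: LatticeCell
    mol_id: tuple[int, tuple[int, int, int]] = (0, (0, 0, 0))

    def __post_init__(self) -> None:
        object.__setattr__(self, "atoms", tuple(self.atoms))
        if not self.atoms:
            raise CrystalError("empty molecule")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @property
    def frac_coords(self) -> np.ndarray:
        return np.array([a.frac for a in self.atoms])

    @property
    def cart_coords(self) -> np.ndarray:
        return self.cell.frac_to_cart(self.frac_coords)

    @property
    def centroid_frac(self) -> np.ndarray:
        return self.frac_coords.mean(axis=0)

    def shifted(self, offset: Sequence[int]) -> "Molecule":
        op_id, cell_off = self.mol_id
        new_off = tuple(np.asarray(cell_off, dtype=int) + np.asarray(offset, dtype=int))
        return Molecule(
            tuple(a.shifted(offset) for a in self.atoms), self.cell, (op_id, new_off)
        )

    def min_distance(self, other: "Molecule") -> float:
        return float(cdist(self.cart_coords, other.cart_coords).min())


@dataclass(frozen=True)
class MolecularCrystal:
    """Cell + symmetry operations + asymmetric unit: the periodic ground truth."""

    cell: LatticeCell
    ops: tuple[SymmetryOp, ...]
    asym_atoms: tuple[Atom, ...]
    name: str = "crystal"

    def __post_init__(self) -> None:
        object.__setattr__(self, "ops", tuple(self.ops))
        object.__setattr__(self, "asym_atoms", tuple(self.asym_atoms))
        if not self.asym_atoms:
            raise CrystalError("asymmetric unit is empty")
        if not any(op.is_identity for op in self.ops):
            raise CrystalError("symmetry operations must contain the identity")

    @property
    def n_sites(self) -> int:
        return len(self.asym_atoms)


_RADIUS_CACHE: dict[str, float | None] = {}


def covalent_radius(symbol: str) -> float | None:
    """Covalent radius in Å, or None for an unrecognized symbol."""
    r = _RADIUS_CACHE.get(symbol, ...)
    if r is not ...:
        return r
    el = gemmi.Element(symbol)
    r = el.covalent_r if el.atomic_number > 0 else None
    _RADIUS_CACHE[symbol] = r
    return r


def frac_to_cart(cell: LatticeCell, frac: np.ndarray) -> np.ndarray:
    return cell.frac_to_cart(frac)


def cart_to_frac(cell: LatticeCell, cart: np.ndarray) -> np.ndarray:
    return cell.cart_to_frac(cart)


def _min_image_distances(
    frac_i: np.ndarray, frac_j: np.ndarray, cell: LatticeCell
) -> tuple[np.ndarray, np.ndarray]:
    """Minimum-image distance matrix and the offset (of j relative to i) realizing it.

    An explicit search over the 27 neighbour offsets is used so that the
    result is exact for skewed (non-orthogonal) cells as well.
    """
    offsets = np.array(list(itertools.product((-1, 0, 1), repeat=3)))
    best = np.full((len(frac_i), len(frac_j)), np.inf)
    best_off = np.zeros((len(frac_i), len(frac_j)), dtype=int)
    ci = cell.frac_to_cart(frac_i)
    for k, off in enumerate(offsets):
        cj = cell.frac_to_cart(frac_j + off)
        d = cdist(ci, cj)
        better = d < best
        best = np.where(better, d, best)
        best_off[better] = k
    return best, offsets[best_off]


def perceive_molecules(
    atoms: Sequence[Atom],
    cell: LatticeCell,
    periodic: bool = False,
    tol: float = BOND_TOLERANCE,
) -> list[Molecule]:
    """Group atoms into bond-connected molecules.

    Atoms i, j are bonded iff their distance does not exceed
    ``(r_cov(i) + r_cov(j)) * (1 + tol)``.  With ``periodic`` on,
    minimum-image distances are used and each molecule is unwrapped so it
    is contiguous in Cartesian space even when it crosses a cell boundary.
    """
    atoms = list(atoms)
    if not atoms:
        return []
    radii = np.array([covalent_radius(a.element) for a in atoms], dtype=float)
    frac = np.array([a.frac for a in atoms])
    cutoff = (radii[:, None] + radii[None, :]) * (1.0 + tol)
    if periodic:
        dist, offsets = _min_image_distances(frac, frac, cell)
    else:
        cart = cell.frac_to_cart(frac)
        dist = cdist(cart, cart)
        offsets = np.zeros((len(atoms), len(atoms), 3), dtype=int)
    bonded = (dist <= cutoff) & ~np.eye(len(atoms), dtype=bool)
    n_comp, labels = connected_components(csr_matrix(bonded), directed=False)

    molecules = []
    for comp in range(n_comp):
        idx = np.flatnonzero(labels == comp)
        shift = {int(idx[0]): np.zeros(3, dtype=int)}
        stack = [int(idx[0])]
        while stack:  # BFS unwrap across periodic boundaries
            i = stack.pop()
            for j in np.flatnonzero(bonded[i]):
                j = int(j)
                if j not in shift:
                    shift[j] = shift[i] + offsets[i, j]
                    stack.append(j)
        mol_atoms = tuple(atoms[i].shifted(shift[i]) for i in sorted(shift))
        first = mol_atoms[0]
        molecules.append(
            Molecule(mol_atoms, cell, (first.op_id, first.cell_offset))
        )
    return molecules


def expand_symmetry(
    crystal: MolecularCrystal, tol: float = BOND_TOLERANCE
) -> list[Molecule]:
    """Generate the unit-cell contents as whole molecules.

    Each symmetry operation is applied to every molecule of the asymmetric
    unit; images are translated so their centroid lies in [0, 1)³ (atoms are
    shifted as a rigid unit, so molecules stay intact), and duplicate images
    on special positions are merged.
    """
    asym_mols = perceive_molecules(crystal.asym_atoms, crystal.cell, periodic=True, tol=tol)
    out: list[Molecule] = []
    for op_id, op in enumerate(crystal.ops):
        for mol in asym_mols:
            new_frac = op.apply(mol.frac_coords)
            shift = -np.floor(new_frac.mean(axis=0)).astype(int)
            new_atoms = tuple(
                replace(a, frac=tuple(f + shift), op_id=op_id, cell_offset=(0, 0, 0))
                for a, f in zip(mol.atoms, new_frac)
            )
            out.append(Molecule(new_atoms, crystal.cell, (op_id, (0, 0, 0))))

    merged: list[Molecule] = []
    for mol in out:
        dup = False
        for kept in merged:
            if len(kept) == len(mol):
                d, _ = _min_image_distances(
                    mol.frac_coords, kept.frac_coords, crystal.cell
                )
                # same molecule if atoms pair up one-to-one within tolerance
                if d.min(axis=1).max() < SPECIAL_POSITION_TOL:
                    dup = True
                    break
        if not dup:
            merged.append(mol)

    for i, mi in enumerate(merged):
        for mj in merged[i + 1 :]:
            d, _ = _min_image_distances(mi.frac_coords, mj.frac_coords, crystal.cell)
            if d.min() < CLASH_DISTANCE:
                raise ClashError(
                    f"molecules {mi.mol_id} and {mj.mol_id} clash "
                    f"({d.min():.2f} Å < {CLASH_DISTANCE} Å)"
                )
    return merged


def build_supercell(crystal: MolecularCrystal, n: int = 9) -> list[Atom]:
    """Atoms of an n×n×n block of unit cells centered on the origin cell.

    ``n`` must be odd so that a central cell exists; offsets range over
    {−(n−1)/2 … +(n−1)/2}³.
    """
    if n < 1 or n % 2 == 0:
        raise CrystalError(f"supercell size must be an odd integer >= 1, got {n}")
    cell_atoms = [a for mol in expand_symmetry(crystal) for a in mol.atoms]
    half = (n - 1) // 2
    rng = range(-half, half + 1)
    return [
        a.shifted(off)
        for off in itertools.product(rng, rng, rng)
        for a in cell_atoms
    ]


# ---------------------------------------------------------------------------
# CIF input (via gemmi) and XYZ output


_CIF_SYMOP_TAGS = (
    "_symmetry_equiv_pos_as_xyz",
    "_space_group_symop_operation_xyz",
)


def read_cif(path: str | Path, name: str | None = None) -> MolecularCrystal:
    """Read cell, symmetry operations and asymmetric-unit sites from a CIF file.

    Both the ``_symmetry_equiv_pos_as_xyz`` and
    ``_space_group_symop_operation_xyz`` dialects are accepted.  The atom
    list must be hydrogen-complete; no hydrogens are added.
    """
    doc = gemmi.cif.read(str(path))
    block = doc.sole_block()
    def num(tag: str) -> float:
        val = block.find_value(tag)
        if val is None:
            raise CrystalError(f"CIF is missing {tag}")
        return float(gemmi.cif.as_number(val))

    cell = LatticeCell(
        num("_cell_length_a"),
        num("_cell_length_b"),
        num("_cell_length_c"),
        num("_cell_angle_alpha"),
        num("_cell_angle_beta"),
        num("_cell_angle_gamma"),
    )

    ops: list[SymmetryOp] = []
    for tag in _CIF_SYMOP_TAGS:
        col = block.find_loop(tag)
        if len(col) > 0:
            ops = [SymmetryOp.from_xyz(gemmi.cif.as_string(v)) for v in col]
            break
    if not ops:
        ops = [SymmetryOp.identity()]

    table = block.find(
        "_atom_site_",
        ["type_symbol", "fract_x", "fract_y", "fract_z"],
    )
    if len(table) == 0:
        table = block.find(
            "_atom_site_", ["label", "fract_x", "fract_y", "fract_z"]
        )
    if len(table) == 0:
        raise CrystalError("CIF has no _atom_site_ loop")
    atoms = []
    for i, row in enumerate(table):
        symbol = "".join(c for c in row[0] if c.isalpha())[:2]
        if covalent_radius(symbol) is None:
            symbol = symbol[0]
        frac = tuple(gemmi.cif.as_number(row[j]) for j in (1, 2, 3))
        atoms.append(Atom(symbol, frac, site_id=i))
    return MolecularCrystal(cell, tuple(ops), tuple(atoms), name=name or block.name)


def write_xyz(
    molecules: Iterable[Molecule] | Molecule, comment: str | None = None
) -> str:
    """Render molecules as XYZ text; the comment line records each mol_id."""
    if isinstance(molecules, Molecule):
        molecules = [molecules]
    molecules = list(molecules)
    atoms = [(a.element, xyz) for m in molecules for a, xyz in zip(m.atoms, m.cart_coords)]
    ids = " ".join(f"{m.mol_id[0]}@{m.mol_id[1]}" for m in molecules)
    lines = [str(len(atoms)), comment if comment is not None else f"mol_id: {ids}"]
    for el, (x, y, z) in atoms:
        lines.append(f"{el:2s} {x:14.8f} {y:14.8f} {z:14.8f}")
    return "\n".join(lines) + "\n"
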