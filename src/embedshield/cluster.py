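"""QM1/QM2/MM embedded-cluster construction.

The cluster model has three layers: a central molecule (QM1, the
asymmetric unit whose NMR properties are computed), the first shell of
neighbouring molecules (QM2, every molecule with at least one atom within
a distance cutoff of QM1), and a point-charge lattice (MM) built from an
n×n×n supercell with the QM members removed.  Charges are assigned per
asymmetric-unit site, so the converged QM1 charges map onto every
periodic image of each site.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .crystal import (
    Atom,
    CrystalError,
    MolecularCrystal,
    Molecule,
    build_supercell,
    expand_symmetry,
)

if TYPE_CHECKING:  # pragma: no cover
    from .embedding import ChargeSet

__all__ = [
    "PointCharge",
    "ClusterModel",
    "FreezeMask",
    "select_qm2",
    "select_qm2_nearest",
    "build_mm_field",
    "build_cluster",
    "freeze_mask",
    "rebuild_cluster",
    "ClusterError",
]

#: a point charge closer than this (Å) to a QM atom is an embedding error
MM_CLEARANCE = 1e-4

#: half-width (in cells) of the bounding supercell searched for QM2 neighbours
QM2_SEARCH_HALFWIDTH = 2


class ClusterError(ValueError):
    """Inconsistent embedded-cluster model."""


@dataclass(frozen=True)
class PointCharge:
    """MM point charge (e) at a Cartesian position (Å).

    The generating site/operation/cell identity is kept so the charge can
    be updated when the asymmetric unit changes.
    """

    q: float
    pos: tuple[float, float, float]
    site_id: int
    op_id: int = 0
    cell_offset: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        pos = tuple(float(x) for x in self.pos)
        if not all(np.isfinite(pos)) or not np.isfinite(self.q):
            raise ClusterError(f"non-finite point charge {self}")
        object.__setattr__(self, "pos", pos)


@dataclass(frozen=True)
class ClusterModel:
    """The embedded model handed to the quantum engine."""

    qm1: Molecule
    qm2: tuple[Molecule, ...]
    mm: tuple[PointCharge, ...]
    crystal: MolecularCrystal
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "qm2", tuple(self.qm2))
        object.__setattr__(self, "mm", tuple(self.mm))
        for mol in self.qm2:
            if mol.mol_id == self.qm1.mol_id:
                raise ClusterError("QM1 molecule also present in the QM2 shell")
        if self.mm:
            qm_xyz = self.qm_coords
            mm_xyz = np.array([pc.pos for pc in self.mm])
            dmin = cdist(mm_xyz, qm_xyz).min()
            if dmin <= MM_CLEARANCE:
                raise ClusterError(
                    f"MM point charge within {dmin:.2e} Å of a QM atom"
                )

    @property
    def qm_molecules(self) -> list[Molecule]:
        return [self.qm1, *self.qm2]

    @property
    def qm_coords(self) -> np.ndarray:
        return np.vstack([m.cart_coords for m in self.qm_molecules])

    @property
    def n_qm_atoms(self) -> int:
        return sum(len(m) for m in self.qm_molecules)


@dataclass(frozen=True)
class FreezeMask:
    """Per-atom relaxation mask over QM1: True = free to move (H only)."""

    free: tuple[bool, ...]
    elements: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.free) != len(self.elements):
            raise ClusterError("mask/element length mismatch")
        for is_free, el in zip(self.free, self.elements):
            if is_free and el != "H":
                raise ClusterError("only hydrogen atoms may be free")

    @property
    def n_free(self) -> int:
        return sum(self.free)


def select_qm2(
    crystal: MolecularCrystal, qm1: Molecule, cutoff: float
) -> list[Molecule]:
    """First shell of molecules with at least one atom within ``cutoff`` Å of QM1.

    All symmetry images in a bounding supercell (±2 cells around the
    origin) are searched; the shell is returned sorted by its minimum
    interatomic distance to QM1 (all atoms, hydrogens included).
    """
    if cutoff < 0:
        raise ClusterError(f"cutoff must be non-negative, got {cutoff}")
    coverage = 2.0 * QM2_SEARCH_HALFWIDTH * crystal.cell.perpendicular_widths().min()
    if cutoff > coverage:
        raise ClusterError(
            f"cutoff {cutoff} Å exceeds the guaranteed coverage radius "
            f"{coverage:.2f} Å of the ±{QM2_SEARCH_HALFWIDTH}-cell search block"
        )
    cell_mols = expand_symmetry(crystal)
    qm1_xyz = qm1.cart_coords
    hw = QM2_SEARCH_HALFWIDTH
    found: list[tuple[float, Molecule]] = []
    for off in itertools.product(range(-hw, hw + 1), repeat=3):
        for mol in cell_mols:
            image = mol.shifted(off)
            if image.mol_id == qm1.mol_id:
                continue
            d = float(cdist(image.cart_coords, qm1_xyz).min())
            if d <= cutoff:
                found.append((d, image))
    found.sort(key=lambda t: (t[0], t[1].mol_id))
    return [mol for _, mol in found]


def select_qm2_nearest(
    crystal: MolecularCrystal, qm1: Molecule, count: int
) -> list[Molecule]:
    """Count-driven alternative to the cutoff criterion: the ``count``
    nearest molecules by minimum interatomic distance.

    Useful when the target is a fixed QM-region size (e.g. "the first
    shell is 12 neighbours") rather than a distance; equivalent to
    ``select_qm2`` with the cutoff set at the count-th neighbour distance.
    """
    if count < 0:
        raise ClusterError(f"count must be non-negative, got {count}")
    coverage = 2.0 * QM2_SEARCH_HALFWIDTH * crystal.cell.perpendicular_widths().min()
    shell = select_qm2(crystal, qm1, coverage)
    if count > len(shell):
        raise ClusterError(
            f"only {len(shell)} molecules within the search block, {count} requested"
        )
    return shell[:count]


def build_mm_field(
    crystal: MolecularCrystal,
    qm_molecules: Sequence[Molecule],
    charges: "ChargeSet",
    n: int = 9,
) -> list[PointCharge]:
    """Point-charge lattice: every atom of the n×n×n supercell except QM members.

    Each charge takes the value fitted for its generating asymmetric site,
    mapped through the atom's ``site_id``; the count therefore satisfies
    ``n³·N_cell − N_QM`` exactly.
    """
    qm_keys = {a.key for m in qm_molecules for a in m.atoms}
    missing = {
        a.site_id
        for m in qm_molecules
        for a in m.atoms
        if a.site_id not in charges.q
    } | {a.site_id for a in crystal.asym_atoms if a.site_id not in charges.q}
    if missing:
        raise ClusterError(f"charge set missing site_ids {sorted(missing)}")
    out = []
    for atom in build_supercell(crystal, n):
        if atom.key in qm_keys:
            continue
        pos = crystal.cell.frac_to_cart(np.asarray(atom.frac))
        out.append(
            PointCharge(
                q=charges.q[atom.site_id],
                pos=tuple(pos),
                site_id=atom.site_id,
                op_id=atom.op_id,
                cell_offset=atom.cell_offset,
            )
        )
    return out


def build_cluster(
    crystal: MolecularCrystal,
    cutoff: float = 3.0,
    charges: "ChargeSet | None" = None,
    n: int = 9,
    qm1: Molecule | None = None,
) -> ClusterModel:
    """Assemble the full QM1/QM2/MM model for one crystal.

    QM1 defaults to the identity-operation molecule of the unit cell.  With
    no charge set the MM layer is left empty (the pre-embedding state used
    to seed charge self-consistency).
    """
    if qm1 is None:
        qm1 = expand_symmetry(crystal)[0]
    qm2 = select_qm2(crystal, qm1, cutoff)
    mm: list[PointCharge] = []
    if charges is not None:
        mm = build_mm_field(crystal, [qm1, *qm2], charges, n=n)
    return ClusterModel(
        qm1=qm1,
        qm2=tuple(qm2),
        mm=tuple(mm),
        crystal=crystal,
        provenance={"crystal": crystal.name, "cutoff": cutoff, "supercell_n": n},
    )


def freeze_mask(cluster: ClusterModel) -> FreezeMask:
    """Relaxation mask freeing exactly the QM1 hydrogens."""
    elements = tuple(cluster.qm1.elements)
    free = tuple(el == "H" for el in elements)
    if not any(free):
        warnings.warn("QM1 contains no hydrogen atoms; freeze mask is empty")
    return FreezeMask(free=free, elements=elements)


def rebuild_cluster(
    cluster: ClusterModel, new_qm1_coords: np.ndarray
) -> ClusterModel:
    """Propagate updated QM1 coordinates through the whole embedding.

    Only atoms free in the hydrogen mask may have moved.  Each site's
    displacement is pulled back to the asymmetric unit through QM1's
    generating operation and pushed forward through every other site
    image's operation, so all QM2 and MM copies move consistently with the
    crystal symmetry.
    """
    new_qm1_coords = np.asarray(new_qm1_coords, dtype=float)
    if new_qm1_coords.shape != (len(cluster.qm1), 3):
        raise ClusterError(
            f"expected {(len(cluster.qm1), 3)} coordinates, got {new_qm1_coords.shape}"
        )
    mask = freeze_mask(cluster)
    old_cart = cluster.qm1.cart_coords
    moved = np.linalg.norm(new_qm1_coords - old_cart, axis=1)
    frozen_moved = [
        i for i, (is_free, d) in enumerate(zip(mask.free, moved)) if not is_free and d > 1e-6
    ]
    if frozen_moved:
        raise ClusterError(f"frozen QM1 atoms moved: indices {frozen_moved}")

    cell = cluster.crystal.cell
    ops = cluster.crystal.ops
    new_frac = cell.cart_to_frac(new_qm1_coords)
    old_frac = cluster.qm1.frac_coords
    # displacement of each asymmetric site in fractional coordinates
    deltas: dict[int, np.ndarray] = {}
    for atom, of, nf in zip(cluster.qm1.atoms, old_frac, new_frac):
        rot = ops[atom.op_id].rotation
        deltas[atom.site_id] = np.linalg.inv(rot) @ (nf - of)

    def moved_molecule(mol: Molecule) -> Molecule:
        new_atoms = []
        for atom in mol.atoms:
            d = deltas.get(atom.site_id)
            if d is None or not np.any(d):
                new_atoms.append(atom)
            else:
                shift = ops[atom.op_id].rotation @ d
                new_atoms.append(replace(atom, frac=tuple(np.asarray(atom.frac) + shift)))
        return Molecule(tuple(new_atoms), mol.cell, mol.mol_id)

    new_qm1 = moved_molecule(cluster.qm1)
    new_qm2 = tuple(moved_molecule(m) for m in cluster.qm2)
    new_mm = []
    for pc in cluster.mm:
        d = deltas.get(pc.site_id)
        if d is None or not np.any(d):
            new_mm.append(pc)
        else:
            shift = cell.frac_to_cart(ops[pc.op_id].rotation @ d)
            new_mm.append(replace(pc, pos=tuple(np.asarray(pc.pos) + shift)))
    return ClusterModel(
        qm1=new_qm1,
        qm2=new_qm2,
        mm=tuple(new_mm),
        crystal=cluster.crystal,
        provenance=dict(cluster.provenance),
    )
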