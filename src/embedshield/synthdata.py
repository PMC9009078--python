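"""Packaged benchmark tables and synthetic toy crystals.

Two kinds of fixture keep the whole pipeline runnable without downloads
or a quantum engine:

* the ¹H and ¹³C benchmark tables for six amino-acid molecular crystals
  (experimental shifts plus isotropic shieldings computed at five levels
  of theory), shipped as checksummed CSV files;
* a deterministic toy-crystal generator (P1 or P2₁, small polar
  molecule, known per-atom reference charges) small enough for
  exhaustive brute-force oracles.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .crystal import (
    Atom,
    ClashError,
    LatticeCell,
    MolecularCrystal,
    SymmetryOp,
    expand_symmetry,
)
from .qm_io import ShieldingTable
from .stats import ExperimentalShifts

__all__ = [
    "AMINO_ACIDS",
    "BENCHMARK_METHODS",
    "ToyCrystalParams",
    "make_toy_crystal",
    "load_benchmark_tables",
    "BenchmarkTables",
    "make_mock_shifts",
    "SynthDataError",
]


class SynthDataError(ValueError):
    """Bad fixture data or toy-crystal parameters."""


#: short system codes → full crystal names
AMINO_ACIDS = {
    "gly": "alpha-glycine",
    "ala": "l-alanine",
    "ser": "l-serine",
    "asp": "l-aspartic acid",
    "cys": "l-cysteine",
    "thr": "l-threonine",
}

#: levels of theory with packaged shieldings
BENCHMARK_METHODS = ("PBE", "TPSS", "B3LYP", "DLPNO-DSD-PBEP86", "DLPNO-MP2")

_CHECKSUMS = {
    "h1_shieldings.csv": "5caf98be44bd1a26f314fb2f4b0946bf818a3f44d0567dc33541618e2106a221",
    "c13_shieldings.csv": "34e4d59f5b844c268d55883092443c96c77e359ec79a41c19aa3cc75b505fa5c",
}

_EXPECTED_COUNTS = {"h1_shieldings.csv": 26, "c13_shieldings.csv": 19}


class BenchmarkTables(NamedTuple):
    shieldings_h: ShieldingTable  # 26 ¹H nuclei × 5 methods
    shieldings_c: ShieldingTable  # 19 ¹³C nuclei × 5 methods
    shifts_h: ExperimentalShifts
    shifts_c: ExperimentalShifts


def _read_fixture(name: str) -> pd.DataFrame:
    ref = resources.files("embedshield.data") / name
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise SynthDataError(
            f"packaged table {name} is corrupted (sha256 {digest[:12]}…)"
        )
    return pd.read_csv(ref.open("r"))


def load_benchmark_tables() -> BenchmarkTables:
    """Load the packaged ¹H/¹³C shielding and shift tables (long format).

    Returns shielding tables with one record per (system, nucleus,
    method) and the matching experimental shifts.  The CSVs are verified
    against frozen checksums; transcription notes live in the package
    documentation.
    """
    out = {}
    for name, element in (("h1_shieldings.csv", "H"), ("c13_shieldings.csv", "C")):
        wide = _read_fixture(name)
        if len(wide) != _EXPECTED_COUNTS[name]:
            raise SynthDataError(
                f"{name}: expected {_EXPECTED_COUNTS[name]} nuclei, got {len(wide)}"
            )
        long = wide.melt(
            id_vars=["system", "nucleus", "delta_exp_ppm"],
            value_vars=list(BENCHMARK_METHODS),
            var_name="method",
            value_name="sigma_ppm",
        )
        long["element"] = element
        out[element] = (
            ShieldingTable(long),
            ExperimentalShifts(wide[["system", "nucleus", "delta_exp_ppm"]]),
        )
    return BenchmarkTables(
        shieldings_h=out["H"][0],
        shieldings_c=out["C"][0],
        shifts_h=out["H"][1],
        shifts_c=out["C"][1],
    )


# ---------------------------------------------------------------------------
# Toy crystals


#: bent 3-atom polar molecule (water-like geometry, Å) with neutral charges
_DEFAULT_TEMPLATE = (
    ("O", (0.000, 0.000, 0.000)),
    ("H", (0.960, 0.000, 0.000)),
    ("H", (-0.240, 0.930, 0.000)),
)
_DEFAULT_CHARGES = (-0.8, 0.4, 0.4)


@dataclass(frozen=True)
class ToyCrystalParams:
    """Parameters of a synthetic molecular crystal.

    ``spacegroup`` is P1 (one molecule per cell) or P21 (2₁ screw axis
    along b, two molecules per cell).  The template molecule is placed at
    a general position with a seed-derived rigid orientation.
    """

    spacegroup: str = "P1"
    cell: LatticeCell = field(default_factory=lambda: LatticeCell(3.8, 4.0, 4.3))
    template: tuple[tuple[str, tuple[float, float, float]], ...] = _DEFAULT_TEMPLATE
    charges: tuple[float, ...] = _DEFAULT_CHARGES
    position: tuple[float, float, float] = (0.31, 0.27, 0.22)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spacegroup not in ("P1", "P21"):
            raise SynthDataError(f"unsupported space group {self.spacegroup!r}")
        if len(self.charges) != len(self.template):
            raise SynthDataError("one reference charge per template atom required")
        if abs(sum(self.charges)) > 1e-9:
            raise SynthDataError(f"template molecule must be neutral: {self.charges}")


def _seed_rotation(seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    # QR of a random matrix gives a uniform-ish deterministic rotation
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def make_toy_crystal(params: ToyCrystalParams = ToyCrystalParams()) -> MolecularCrystal:
    """Deterministic toy molecular crystal from the given parameters.

    The template is rotated rigidly (seed-derived), converted to
    fractional coordinates at the requested general position, and paired
    with the space-group operations.  Symmetry expansion validates that
    the packing is clash-free; a molecule too large for the cell is
    rejected there.
    """
    rot = _seed_rotation(params.seed)
    cart = np.array([xyz for _, xyz in params.template]) @ rot.T
    frac = params.cell.cart_to_frac(cart) + np.asarray(params.position)
    atoms = tuple(
        Atom(el, tuple(f), site_id=i)
        for i, ((el, _), f) in enumerate(zip(params.template, frac))
    )
    ops = [SymmetryOp.identity()]
    if params.spacegroup == "P21":
        ops.append(SymmetryOp.from_xyz("-x, y+1/2, -z"))
    crystal = MolecularCrystal(
        params.cell, tuple(ops), atoms, name=f"toy-{params.spacegroup}-{params.seed}"
    )
    mols = expand_symmetry(crystal)  # raises ClashError on molecular overlap
    # a cell smaller than the molecule makes periodic images fall within
    # bonding distance, silently rewriting the geometry — reject it
    from scipy.spatial.distance import pdist

    ref = np.sort(pdist(cart))
    for mol in mols:
        if len(mol) != len(params.template) or not np.allclose(
            np.sort(pdist(mol.cart_coords)), ref, atol=1e-6
        ):
            raise ClashError(
                f"molecule does not fit in the {params.cell.a:.2f} Å cell: "
                "periodic images overlap the template geometry"
            )
    return crystal


def make_mock_shifts(
    sigma: ShieldingTable,
    a0: float = -1.0,
    b0: float = 30.0,
    noise: float = 0.0,
    seed: int = 0,
) -> ExperimentalShifts:
    """Synthetic "experimental" shifts consistent with a planted line.

    δ_exp = (σ + ε − b0)/a0 with ε ~ N(0, noise²), so fitting σ on δ
    should recover (a0, b0) up to the noise level — the end-to-end
    parameter-recovery check for the mock pipeline.
    """
    rng = np.random.default_rng(seed)
    f = sigma.frame
    eps = rng.normal(0.0, noise, size=len(f)) if noise > 0 else np.zeros(len(f))
    delta = (f["sigma_ppm"].to_numpy(dtype=float) + eps - b0) / a0
    return ExperimentalShifts(
        pd.DataFrame(
            {
                "system": f["system"],
                "nucleus": f["nucleus"],
                "delta_exp_ppm": delta,
            }
        )
    )
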