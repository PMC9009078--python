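"""Contract with the external quantum engine.

This module owns everything that crosses the boundary to the
electronic-structure code: byte-deterministic input decks (ORCA-style
dialect), the external point-charge file, parsing of shielding output,
and a deterministic mock backend whose shieldings respond to the
electrostatic environment — enough structure for the whole pipeline to
run and be tested without any quantum engine.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cluster import ClusterModel
from .embedding import ANGSTROM_PER_BOHR, ChargeSet, coulomb_potential

__all__ = [
    "METHODS",
    "MethodSpec",
    "ShieldingTable",
    "write_nmr_input",
    "write_pointcharge_file",
    "write_shielding_output",
    "parse_shieldings",
    "mock_shieldings",
    "QMIOError",
]


class QMIOError(ValueError):
    """Invalid engine input/output."""


#: recognized electronic-structure methods; the last two request
#: post-SCF correlation and hence DLPNO/multilevel keywords
METHODS = ("PBE", "TPSS", "B3LYP", "DSD-PBEP86", "MP2")
_CORRELATED = ("DSD-PBEP86", "MP2")
_DFT = ("PBE", "TPSS", "B3LYP", "DSD-PBEP86")


@dataclass(frozen=True)
class MethodSpec:
    """Electronic-structure settings encoded into the input deck.

    ``pno_levels`` assigns the pair-natural-orbital accuracy tier per
    electron-pair class: pairs touching the central (QM1) fragment versus
    all remaining pairs.
    """

    method: str
    qm1_basis: str = "pcSseg-3"
    qm2_basis: str = "def2-TZVP"
    dispersion: bool = True
    ri: str = "RIJCOSX"
    grid: str = "DefGrid3"
    pno_levels: tuple[str, str] = ("NormalPNO", "LoosePNO")

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise QMIOError(
                f"unsupported method {self.method!r}; expected one of {METHODS}"
            )
        if not self.qm1_basis or not self.qm2_basis:
            raise QMIOError("basis sets must be non-empty")
        if self.method == "MP2" and self.dispersion:
            raise QMIOError("dispersion correction applies to DFT methods only")

    @property
    def is_correlated(self) -> bool:
        return self.method in _CORRELATED


class ShieldingTable:
    """Isotropic shieldings keyed by (system, nucleus, method), in ppm.

    Thin wrapper over a pandas DataFrame with columns
    ``system, nucleus, element, method, sigma_ppm`` enforcing key
    uniqueness and finite values.
    """

    COLUMNS = ["system", "nucleus", "element", "method", "sigma_ppm"]

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in frame.columns]
        if missing:
            raise QMIOError(f"shielding table missing columns {missing}")
        frame = frame[self.COLUMNS].reset_index(drop=True)
        if not np.isfinite(frame["sigma_ppm"].to_numpy(dtype=float)).all():
            raise QMIOError("non-finite shielding value")
        keys = frame[["system", "nucleus", "method"]]
        if keys.duplicated().any():
            dup = keys[keys.duplicated()].iloc[0].tolist()
            raise QMIOError(f"duplicate shielding record for {tuple(dup)}")
        self.frame = frame

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, str, str, float]]
    ) -> "ShieldingTable":
        return cls(pd.DataFrame(list(records), columns=cls.COLUMNS))

    @classmethod
    def from_csv(cls, path: str | Path) -> "ShieldingTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ShieldingTable):
            return NotImplemented
        a = self.frame.sort_values(["system", "nucleus", "method"]).reset_index(drop=True)
        b = other.frame.sort_values(["system", "nucleus", "method"]).reset_index(drop=True)
        return a.equals(b)

    def select(self, method: str | None = None, element: str | None = None) -> "ShieldingTable":
        f = self.frame
        if method is not None:
            f = f[f["method"] == method]
        if element is not None:
            f = f[f["element"] == element]
        if f.empty:
            raise QMIOError(f"no records for method={method!r} element={element!r}")
        return ShieldingTable(f)

    @property
    def methods(self) -> list[str]:
        return sorted(self.frame["method"].unique())

    def sigma(self, system: str, nucleus: str, method: str | None = None) -> float:
        f = self.frame
        sel = (f["system"] == system) & (f["nucleus"] == nucleus)
        if method is not None:
            sel &= f["method"] == method
        hit = f[sel]
        if len(hit) != 1:
            raise QMIOError(
                f"expected one record for ({system}, {nucleus}, {method}), got {len(hit)}"
            )
        return float(hit["sigma_ppm"].iloc[0])

    def with_method(self, method: str) -> "ShieldingTable":
        f = self.frame.copy()
        f["method"] = method
        return ShieldingTable(f)


# ---------------------------------------------------------------------------
# Input decks


def _atom_lines(cluster: ClusterModel, spec: MethodSpec) -> list[str]:
    lines = []
    for frag, mols, basis in (
        (1, [cluster.qm1], spec.qm1_basis),
        (2, list(cluster.qm2), spec.qm2_basis),
    ):
        for mol in mols:
            for atom, (x, y, z) in zip(mol.atoms, mol.cart_coords):
                lines.append(
                    f"  {atom.element:<2s}({frag}) {x:14.6f} {y:14.6f} {z:14.6f}"
                    f'  NewGTO "{basis}" end'
                )
    return lines


def write_nmr_input(
    cluster: ClusterModel,
    spec: MethodSpec,
    pc_filename: str = "field.pc",
    charge: int = 0,
    multiplicity: int = 1,
    qm1_only: bool = True,
) -> str:
    """Engine input deck for a GIAO shielding calculation on the cluster.

    QM1 atoms are listed first with fragment tag 1 and the large basis,
    QM2 atoms with fragment tag 2 and the smaller basis.  The NMR block
    requests shieldings for fragment-1 nuclei only (the central molecule)
    unless ``qm1_only`` is off.  For correlated methods the multilevel
    DLPNO keywords are emitted: pairs touching fragment 1 at the tighter
    PNO level, the rest at the looser one.  Output is byte-deterministic
    for a fixed (cluster, spec).
    """
    kw = [spec.method if spec.method != "DSD-PBEP86" else "DSD-PBEP86"]
    if spec.method == "MP2":
        kw[0] = "DLPNO-MP2"
    elif spec.method == "DSD-PBEP86":
        kw.insert(0, "DLPNO")
    if spec.dispersion and spec.method in _DFT:
        kw.append("D3BJ")
    kw += [spec.ri, spec.grid, "NMR"]
    out = io.StringIO()
    out.write("! " + " ".join(kw) + "\n")
    out.write(f'%pointcharges "{pc_filename}"\n')
    if spec.is_correlated:
        tight, loose = spec.pno_levels
        out.write("%mp2\n")
        out.write("  DLPNO true\n")
        out.write("  MultiLevel true\n")
        out.write(f'  Fragment1PairLevel "{tight}"\n')
        out.write(f'  DefaultPairLevel "{loose}"\n')
        out.write("end\n")
    out.write("%eprnmr\n")
    if qm1_only:
        n_qm1 = len(cluster.qm1)
        idx = ",".join(str(i) for i in range(n_qm1))
        out.write(f"  Nuclei = {idx} {{ shift }}\n")
    else:
        out.write("  Nuclei = all { shift }\n")
    out.write("end\n")
    out.write(f"* xyz {charge} {multiplicity}\n")
    for line in _atom_lines(cluster, spec):
        out.write(line + "\n")
    out.write("*\n")
    return out.getvalue()


def write_pointcharge_file(charges: Sequence) -> str:
    """External point-charge file: count line, then ``q x y z`` per charge.

    Charges in e, coordinates in Å, fixed 6-decimal formatting.
    """
    lines = [str(len(charges))]
    for pc in charges:
        x, y, z = pc.pos
        lines.append(f"{pc.q:.6f} {x:.6f} {y:.6f} {z:.6f}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Shielding output


_NUCLEUS_RE = re.compile(
    r"^\s*Nucleus\s+(\d+)([A-Z][a-z]?)\s*:?\s*$", re.MULTILINE
)
_ISO_RE = re.compile(r"^\s*Isotropic shielding \(ppm\)\s*:\s*(-?[\d.]+)\s*$")


def write_shielding_output(
    table: ShieldingTable, index_map: Sequence[tuple[int, str]] | None = None
) -> str:
    """Render a shielding table in the engine-output text format parsed below."""
    lines = ["CHEMICAL SHIELDINGS (ppm)", ""]
    for i, row in table.frame.iterrows():
        idx = int(re.sub(r"\D", "", row["nucleus"]) or i)
        lines.append(f" Nucleus {idx}{row['element']} :")
        lines.append(f"   Isotropic shielding (ppm) : {row['sigma_ppm']:.6f}")
        lines.append("")
    return "\n".join(lines) + "\n"


def parse_shieldings(
    text: str, system: str = "cluster", method: str = "engine"
) -> ShieldingTable:
    """Parse isotropic shieldings from engine output text.

    Each nucleus block must contain exactly one isotropic-shielding line;
    nucleus labels are formed as element + index and must be unique.
    """
    records = []
    seen = set()
    matches = list(_NUCLEUS_RE.finditer(text))
    if not matches:
        raise QMIOError("no nucleus blocks found in engine output")
    for k, m in enumerate(matches):
        idx, element = int(m.group(1)), m.group(2)
        label = f"{element}{idx}"
        if label in seen:
            raise QMIOError(f"duplicate nucleus block for {label}")
        seen.add(label)
        end = matches[k + 1].start() if k + 1 < len(matches) else len(text)
        block = text[m.end():end]
        vals = [
            _ISO_RE.match(line)
            for line in block.splitlines()
            if _ISO_RE.match(line)
        ]
        if len(vals) != 1:
            raise QMIOError(
                f"nucleus {label}: expected one isotropic-shielding line, "
                f"found {len(vals)}"
            )
        records.append((system, label, element, method, float(vals[0].group(1))))
    return ShieldingTable.from_records(records)


# ---------------------------------------------------------------------------
# Mock backend


#: bare-nucleus baseline shieldings (ppm) for the mock backend
MOCK_SIGMA0 = {"H": 30.0, "C": 150.0, "N": 200.0, "O": 280.0, "S": 550.0}

#: environment response (ppm per atomic unit of external potential); sized
#: so typical crystal fields shift the mock shieldings by a few ppm
MOCK_RESPONSE = {"H": 40.0, "C": 120.0, "N": 90.0, "O": 80.0, "S": 60.0}


def mock_shieldings(
    cluster: ClusterModel,
    charges: ChargeSet | None = None,
    system: str = "toy",
    method: str = "MOCK",
) -> ShieldingTable:
    """Deterministic analytic shielding model with environment sensitivity.

    For each QM1 nucleus, σ = σ₀(element) + c(element)·V, where V is the
    Coulomb potential (atomic units) at the nucleus from all QM2 partial
    charges (mapped from the converged charge set) and all MM point
    charges.  With no environment σ equals the element baseline exactly;
    the model is invariant under rigid translation/rotation of the whole
    cluster.
    """
    xyz = cluster.qm1.cart_coords
    src_pos: list[np.ndarray] = []
    src_q: list[float] = []
    if charges is not None:
        for mol in cluster.qm2:
            for atom, pos in zip(mol.atoms, mol.cart_coords):
                if atom.site_id not in charges.q:
                    raise QMIOError(f"charge set missing site_id {atom.site_id}")
                src_pos.append(pos)
                src_q.append(charges.q[atom.site_id])
    for pc in cluster.mm:
        src_pos.append(np.asarray(pc.pos))
        src_q.append(pc.q)
    if src_pos:
        v = coulomb_potential(xyz, np.array(src_q), np.vstack(src_pos))
    else:
        v = np.zeros(len(xyz))
    records = []
    for i, (atom, vi) in enumerate(zip(cluster.qm1.atoms, v)):
        el = atom.element
        sigma0 = MOCK_SIGMA0.get(el, 100.0)
        c = MOCK_RESPONSE.get(el, 60.0)
        records.append((system, f"{el}{i}", el, method, sigma0 + c * float(vi)))
    return ShieldingTable.from_records(records)
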