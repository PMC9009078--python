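"""Snapshot machinery for the hydrogen-only MD vibrational estimate.

The protocol: run constrained MD in which only the QM1 hydrogens move,
draw evenly spaced snapshots after an equilibration period, compute
shieldings for each snapshot, and use the difference between the
snapshot average and the rigid-structure value as an additive
vibrational correction per nucleus.  The MD propagation itself is
external (GFN2-xTB); a Gaussian-jitter stand-in generates synthetic
trajectories with the same interface for desk-scale runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cluster import ClusterModel, freeze_mask
from .qm_io import QMIOError, ShieldingTable

__all__ = [
    "SnapshotSchedule",
    "DEFAULT_SCHEDULE",
    "snapshot_times",
    "jitter_trajectory",
    "average_shieldings",
    "diff_correction",
    "read_xyz_frames",
    "write_xyz_frames",
    "DynamicsError",
]


class DynamicsError(ValueError):
    """Invalid snapshot schedule or trajectory."""


@dataclass(frozen=True)
class SnapshotSchedule:
    """Sampling plan for an MD run: time step, length, equilibration, snapshots."""

    dt_fs: float = 1.0
    total_ps: float = 40.0
    equil_ps: float = 1.0
    count: int = 100
    interval_ps: float = 0.3

    def __post_init__(self) -> None:
        vals = (self.dt_fs, self.total_ps, self.equil_ps, self.count, self.interval_ps)
        if any(v <= 0 for v in vals):
            raise DynamicsError(f"schedule values must be positive: {self}")
        if self.equil_ps + self.count * self.interval_ps > self.total_ps + 1e-9:
            raise DynamicsError(
                f"schedule overruns the run: equil + count*interval = "
                f"{self.equil_ps + self.count * self.interval_ps} ps > {self.total_ps} ps"
            )
        dt_ps = self.dt_fs / 1000.0
        for name, v in (("equil", self.equil_ps), ("interval", self.interval_ps)):
            if abs(v / dt_ps - round(v / dt_ps)) > 1e-9:
                raise DynamicsError(f"{name} ({v} ps) is not a multiple of dt ({self.dt_fs} fs)")


#: default protocol: 1 fs steps, 40 ps run, 1 ps equilibration,
#: 100 snapshots every 0.3 ps (first at 1.3 ps, last at 31.0 ps)
DEFAULT_SCHEDULE = SnapshotSchedule()


def snapshot_times(schedule: SnapshotSchedule) -> np.ndarray:
    """Snapshot times in ps: t_k = equil + k·interval for k = 1…count."""
    k = np.arange(1, schedule.count + 1)
    return schedule.equil_ps + k * schedule.interval_ps


def jitter_trajectory(
    cluster: ClusterModel,
    amplitude: float,
    seed: int,
    count: int = 100,
) -> list[np.ndarray]:
    """Synthetic hydrogen-only trajectory for the QM1 molecule.

    Each snapshot displaces every QM1 hydrogen by an independent isotropic
    Gaussian offset of standard deviation ``amplitude`` (Å per coordinate);
    heavy atoms stay fixed.  Deterministic for a fixed seed.
    """
    if amplitude < 0:
        raise DynamicsError(f"amplitude must be non-negative, got {amplitude}")
    rng = np.random.default_rng(seed)
    base = cluster.qm1.cart_coords
    free = np.array(freeze_mask(cluster).free)
    frames = []
    for _ in range(count):
        coords = base.copy()
        coords[free] += rng.normal(0.0, amplitude, size=(int(free.sum()), 3))
        frames.append(coords)
    return frames


def _check_same_nuclei(tables: Sequence[ShieldingTable]) -> pd.Index:
    keys = [
        pd.MultiIndex.from_frame(t.frame[["system", "nucleus"]]).sort_values()
        for t in tables
    ]
    for k in keys[1:]:
        if not k.equals(keys[0]):
            raise DynamicsError("shielding tables cover different nucleus sets")
    return keys[0]


def average_shieldings(
    tables: Sequence[ShieldingTable], method: str | None = None
) -> ShieldingTable:
    """Arithmetic per-nucleus mean over snapshot shielding tables."""
    if not tables:
        raise DynamicsError("no shielding tables to average")
    _check_same_nuclei(tables)
    stacked = pd.concat([t.frame for t in tables], ignore_index=True)
    grouped = (
        stacked.groupby(["system", "nucleus", "element"], as_index=False)["sigma_ppm"]
        .mean()
    )
    grouped["method"] = method if method is not None else tables[0].frame["method"].iloc[0]
    out = ShieldingTable(grouped)
    out.n_samples = len(tables)
    return out


def diff_correction(
    static: ShieldingTable, md_mean: ShieldingTable, method: str = "DIFF"
) -> ShieldingTable:
    """Per-nucleus vibrational correction Δσ = ⟨σ⟩_MD − σ_rigid.

    Adding the result to the rigid table reproduces the MD average
    exactly; the correction is computed once (at a cheap method) and can
    be applied additively to tables from any level of theory.
    """
    _check_same_nuclei([static, md_mean])
    key = ["system", "nucleus"]
    s = static.frame.set_index(key)
    m = md_mean.frame.set_index(key)
    out = s.copy()
    out["sigma_ppm"] = m["sigma_ppm"] - s["sigma_ppm"]
    out["method"] = method
    return ShieldingTable(out.reset_index())


# ---------------------------------------------------------------------------
# Multi-frame XYZ trajectories (external-MD exchange format)


def write_xyz_frames(
    frames: Sequence[np.ndarray], elements: Sequence[str], comments: Sequence[str] | None = None
) -> str:
    n = len(elements)
    chunks = []
    for i, coords in enumerate(frames):
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (n, 3):
            raise DynamicsError(f"frame {i}: expected shape {(n, 3)}, got {coords.shape}")
        comment = comments[i] if comments else f"frame {i}"
        lines = [str(n), comment]
        lines += [
            f"{el:2s} {x:14.8f} {y:14.8f} {z:14.8f}"
            for el, (x, y, z) in zip(elements, coords)
        ]
        chunks.append("\n".join(lines))
    return "\n".join(chunks) + "\n"


def read_xyz_frames(text: str) -> tuple[list[str], list[np.ndarray]]:
    lines = text.splitlines()
    frames: list[np.ndarray] = []
    elements: list[str] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].strip())
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise DynamicsError("truncated XYZ frame")
        els = [ln.split()[0] for ln in block]
        coords = np.array([[float(v) for v in ln.split()[1:4]] for ln in block])
        if not elements:
            elements = els
        elif els != elements:
            raise DynamicsError("inconsistent elements across XYZ frames")
        frames.append(coords)
        i += 2 + n
    if not frames:
        raise DynamicsError("no frames in XYZ text")
    return elements, frames
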