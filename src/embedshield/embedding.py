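"""Self-consistent point-charge embedding.

The MM lattice charges are required to equal the atomic charges of the
central molecule (QM1) computed *in the field of that same lattice*.  The
fixed point is found by iteration: charges are first computed in vacuum,
mapped onto every equivalent MM site, recomputed in the resulting field,
and so on until the largest per-atom change drops below a threshold
(0.01 e by default).

The actual charge model is pluggable (``ChargeProvider``).  A real
calculation delegates to an external quantum engine returning
ESP-fitted (CHELPG) charges; for testing, deterministic mock providers
with known fixed points are supplied, together with the constrained
least-squares ESP-fitting machinery they use.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence

import gemmi
import numpy as np
from scipy.spatial.distance import cdist

from .cluster import PointCharge, build_mm_field
from .crystal import MolecularCrystal, Molecule

__all__ = [
    "ANGSTROM_PER_BOHR",
    "ChargeSet",
    "ChargeProvider",
    "ConstantChargeProvider",
    "LinearResponseProvider",
    "PolarizableEspProvider",
    "converge_charges",
    "esp_fit_charges",
    "chelpg_grid",
    "coulomb_potential",
    "ConvergenceError",
    "EmbeddingError",
]

ANGSTROM_PER_BOHR = 0.529177210903

#: neutrality bookkeeping tolerance (e)
CHARGE_SUM_TOL = 1e-6


class EmbeddingError(ValueError):
    """Invalid embedding state or input."""


class ConvergenceError(RuntimeError):
    """Charge self-consistency did not converge; carries the iteration history."""

    def __init__(self, message: str, history: list[dict[int, float]]):
        super().__init__(message)
        self.history = history


@dataclass(frozen=True)
class ChargeSet:
    """Per-asymmetric-site charges with the self-consistency history.

    ``history[k]`` is the charge map after iteration k; ``history[-1] == q``.
    """

    q: dict[int, float]
    iteration: int = 0
    history: tuple[dict[int, float], ...] = ()
    total_charge: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "q", dict(self.q))
        object.__setattr__(self, "history", tuple(dict(h) for h in self.history))
        if abs(sum(self.q.values()) - self.total_charge) > CHARGE_SUM_TOL:
            raise EmbeddingError(
                f"charges sum to {sum(self.q.values()):.8f}, "
                f"expected {self.total_charge}"
            )

    def as_array(self, site_ids: Sequence[int]) -> np.ndarray:
        return np.array([self.q[s] for s in site_ids])


class ChargeProvider(Protocol):
    """Charge model contract: (QM1 molecule, MM field) → per-atom charges.

    Implementations must be deterministic for fixed input and return
    charges summing to the molecular total charge.
    """

    def __call__(
        self, qm1: Molecule, mm: Sequence[PointCharge]
    ) -> np.ndarray: ...  # pragma: no cover


def coulomb_potential(
    points: np.ndarray, charges: np.ndarray, sources: np.ndarray
) -> np.ndarray:
    """Electrostatic potential (hartree/e) at ``points`` from point ``sources`` in Å."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if len(charges) == 0:
        return np.zeros(len(points))
    d = cdist(points, np.atleast_2d(sources)) / ANGSTROM_PER_BOHR
    return (np.asarray(charges) / d).sum(axis=1)


def esp_fit_charges(
    positions: np.ndarray,
    grid_points: np.ndarray,
    potentials: np.ndarray,
    total_charge: float = 0.0,
) -> np.ndarray:
    """Least-squares atomic charges reproducing a potential on a grid.

    Minimizes Σ_g (V_g − Σ_i q_i/|r_g − r_i|)² subject to Σ q_i equalling
    the total molecular charge (Lagrange multiplier).  Distances enter the
    Coulomb kernel in bohr, so ``potentials`` are in atomic units.  For a
    rank-deficient system (degenerate symmetric grids) the minimum-norm
    solution is returned with a warning.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    grid_points = np.atleast_2d(np.asarray(grid_points, dtype=float))
    potentials = np.asarray(potentials, dtype=float)
    n = len(positions)
    if len(grid_points) < n:
        raise EmbeddingError(
            f"need at least {n} grid points for {n} atoms, got {len(grid_points)}"
        )
    A = ANGSTROM_PER_BOHR / cdist(grid_points, positions)
    # KKT system for min ||Aq - V||^2  s.t.  1.q = Q
    kkt = np.zeros((n + 1, n + 1))
    kkt[:n, :n] = 2.0 * A.T @ A
    kkt[:n, n] = 1.0
    kkt[n, :n] = 1.0
    rhs = np.concatenate([2.0 * A.T @ potentials, [total_charge]])
    if np.linalg.matrix_rank(kkt) < n + 1:
        warnings.warn("rank-deficient ESP grid; returning minimum-norm charges")
        sol = np.linalg.lstsq(kkt, rhs, rcond=None)[0]
    else:
        sol = np.linalg.solve(kkt, rhs)
    return sol[:n]


def chelpg_grid(
    positions: np.ndarray,
    elements: Sequence[str],
    spacing: float = 0.5,
    inner_scale: float = 1.4,
    outer_radius: float = 2.8,
) -> np.ndarray:
    """Regular-lattice ESP sampling grid around a molecule.

    Points on a cubic lattice (``spacing`` Å) are kept if they lie outside
    ``inner_scale``×vdW-radius of every atom and within ``outer_radius`` Å
    of at least one atom.  This mirrors the common grid-based ESP-fitting
    setup; the external engine's own grid need not be identical.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    vdw = np.array([gemmi.Element(el).vdw_r for el in elements])
    lo = positions.min(axis=0) - outer_radius
    hi = positions.max(axis=0) + outer_radius
    axes = [np.arange(lo[k], hi[k] + spacing / 2, spacing) for k in range(3)]
    pts = np.array(list(itertools.product(*axes)))
    d = cdist(pts, positions)
    keep = (d >= inner_scale * vdw).all(axis=1) & (d <= outer_radius).any(axis=1)
    return pts[keep]


# ---------------------------------------------------------------------------
# Mock providers


@dataclass(frozen=True)
class ConstantChargeProvider:
    """Returns the same charges regardless of the field (immediate fixed point)."""

    charges: tuple[float, ...]

    def __call__(self, qm1: Molecule, mm: Sequence[PointCharge]) -> np.ndarray:
        return np.asarray(self.charges, dtype=float)


def _site_charges_from_field(
    q0: np.ndarray, site_ids: Sequence[int], mm: Sequence[PointCharge]
) -> np.ndarray:
    """Read back per-site charges from the MM lattice (vacuum → q0)."""
    if not mm:
        return np.asarray(q0, dtype=float)
    by_site = {}
    for pc in mm:
        by_site.setdefault(pc.site_id, pc.q)
    return np.array([by_site.get(s, q) for s, q in zip(site_ids, q0)])


@dataclass(frozen=True)
class LinearResponseProvider:
    """Linear charge response q' = q0 + λ·M·q with an analytic fixed point.

    The previous iteration's charges are read back from the MM lattice.
    For spectral radius(λM) < 1 the iteration contracts to the solution of
    (I − λM) q = q0, which tests can solve independently.  ``response``
    must have zero column sums so neutrality is conserved.
    """

    q0: tuple[float, ...]
    response: tuple[tuple[float, ...], ...]
    lam: float = 0.5

    def __call__(self, qm1: Molecule, mm: Sequence[PointCharge]) -> np.ndarray:
        q0 = np.asarray(self.q0, dtype=float)
        M = np.asarray(self.response, dtype=float)
        site_ids = [a.site_id for a in qm1.atoms]
        q_prev = _site_charges_from_field(q0, site_ids, mm)
        return q0 + self.lam * (M @ q_prev)

    def fixed_point(self) -> np.ndarray:
        q0 = np.asarray(self.q0, dtype=float)
        M = np.asarray(self.response, dtype=float)
        return np.linalg.solve(np.eye(len(q0)) - self.lam * M, q0)


@dataclass(frozen=True)
class PolarizableEspProvider:
    """Physically flavoured mock: polarizable charges re-fitted from their own ESP.

    Each atom carries a reference charge and an isotropic response
    coefficient; the "true" charges shift linearly with the external MM
    potential at the nuclei (projected so the total charge is conserved),
    an ESP is generated from them on a grid around the molecule, and the
    returned charges are the constrained least-squares fit to that ESP —
    exercising the same fitting machinery a real CHELPG backend would.
    """

    ref_charges: tuple[float, ...]
    polarizability: float = 0.05
    grid_spacing: float = 0.5

    def __call__(self, qm1: Molecule, mm: Sequence[PointCharge]) -> np.ndarray:
        q_ref = np.asarray(self.ref_charges, dtype=float)
        xyz = qm1.cart_coords
        if mm:
            mm_pos = np.array([pc.pos for pc in mm])
            mm_q = np.array([pc.q for pc in mm])
            v_ext = coulomb_potential(xyz, mm_q, mm_pos)
        else:
            v_ext = np.zeros(len(xyz))
        dq = self.polarizability * (v_ext - v_ext.mean())  # neutrality preserved
        q_true = q_ref + dq
        grid = chelpg_grid(xyz, qm1.elements, spacing=self.grid_spacing)
        v_grid = coulomb_potential(grid, q_true, xyz)
        return esp_fit_charges(xyz, grid, v_grid, total_charge=q_ref.sum())


# ---------------------------------------------------------------------------
# Self-consistency loop


def converge_charges(
    provider: ChargeProvider,
    crystal: MolecularCrystal,
    qm1: Molecule,
    qm2: Sequence[Molecule] = (),
    n: int = 9,
    tol: float = 0.01,
    max_iter: int = 50,
    metric: str = "max",
) -> ChargeSet:
    """Iterate QM1 charges against the MM lattice to self-consistency.

    Iteration 0 evaluates the provider with an empty MM field; each later
    iteration rebuilds the n×n×n point-charge lattice from the previous
    charges and re-evaluates.  Convergence is declared when the per-atom
    maximum absolute change (or RMS change with ``metric="rms"``) is at
    most ``tol``.  Charges are carried at full precision between
    iterations.
    """
    if metric not in ("max", "rms"):
        raise EmbeddingError(f"unknown convergence metric {metric!r}")
    site_ids = [a.site_id for a in qm1.atoms]
    if len(set(site_ids)) != len(site_ids):
        raise EmbeddingError("QM1 atoms do not map to distinct asymmetric sites")

    def to_map(arr: np.ndarray) -> dict[int, float]:
        return {s: float(v) for s, v in zip(site_ids, arr)}

    q = np.asarray(provider(qm1, []), dtype=float)
    total = float(q.sum())
    history = [to_map(q)]
    qm_molecules = [qm1, *qm2]
    for iteration in range(1, max_iter + 1):
        charges = ChargeSet(to_map(q), iteration - 1, tuple(history), total_charge=total)
        mm = build_mm_field(crystal, qm_molecules, charges, n=n)
        q_new = np.asarray(provider(qm1, mm), dtype=float)
        if abs(q_new.sum() - total) > CHARGE_SUM_TOL:
            raise EmbeddingError(
                f"provider broke neutrality at iteration {iteration}: "
                f"sum {q_new.sum():.8f} != {total:.8f}"
            )
        change = np.abs(q_new - q)
        delta = float(change.max()) if metric == "max" else float(
            np.sqrt(np.mean(change**2))
        )
        history.append(to_map(q_new))
        q = q_new
        if delta <= tol:
            return ChargeSet(to_map(q), iteration, tuple(history), total_charge=total)
    raise ConvergenceError(
        f"charge self-consistency not reached in {max_iter} iterations "
        f"(last change {delta:.4f} > tol {tol})",
        history,
    )
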