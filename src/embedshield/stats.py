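"""Shielding-to-shift evaluation layer.

Computed isotropic shieldings σ are referenced to experimental shifts δ
through an ordinary least-squares fit σ = aδ + b (shielding as the
response).  Predicted shifts follow by inversion, δ_calc = (σ − b)/a,
which removes the systematic bias of each electronic-structure method;
the residual statistics (MAE, MaxAE with its worst nucleus, SDE, MSE)
quantify what remains.  Absolute referencing against a computed standard
(TMS) is provided for comparison, along with additive correction
schemes (molecular higher-level Δσ, spin–orbit Δσ, MD vibrational Δσ).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .qm_io import QMIOError, ShieldingTable

__all__ = [
    "ExperimentalShifts",
    "RegressionReport",
    "ErrorMetrics",
    "fit_shieldings",
    "predict_shifts",
    "error_metrics",
    "reference_shifts",
    "apply_correction",
    "average_tables",
    "report_tables",
    "render_report",
    "StatsError",
]


class StatsError(ValueError):
    """Invalid evaluation input."""


class ExperimentalShifts:
    """Experimental chemical shifts keyed by (system, nucleus), in ppm."""

    COLUMNS = ["system", "nucleus", "delta_exp_ppm"]

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in frame.columns]
        if missing:
            raise StatsError(f"shift table missing columns {missing}")
        frame = frame[self.COLUMNS].reset_index(drop=True)
        if frame[["system", "nucleus"]].duplicated().any():
            raise StatsError("duplicate (system, nucleus) in experimental shifts")
        self.frame = frame

    @classmethod
    def from_records(cls, records) -> "ExperimentalShifts":
        return cls(pd.DataFrame(list(records), columns=cls.COLUMNS))

    @classmethod
    def from_csv(cls, path: str | Path) -> "ExperimentalShifts":
        return cls(pd.read_csv(path))

    def __len__(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class ErrorMetrics:
    mae: float
    maxae: float
    maxae_label: str
    sde: float
    mse: float


@dataclass(frozen=True)
class RegressionReport:
    """Linear-referencing fit and residual statistics for one method."""

    a: float  # slope, unitless
    b: float  # intercept, ppm
    r2: float
    mae: float
    maxae: float
    maxae_label: str
    sde: float
    mse: float
    n: int
    method: str = ""

    def __post_init__(self) -> None:
        if self.n < 3:
            raise StatsError(f"regression needs n >= 3, got {self.n}")
        if not (self.maxae >= self.mae >= 0):
            raise StatsError("expected MaxAE >= MAE >= 0")


def predict_shifts(sigma: np.ndarray, a: float, b: float) -> np.ndarray:
    """Invert the referencing line: δ_calc = (σ − b)/a."""
    if a == 0:
        raise StatsError("slope a = 0 cannot be inverted")
    return (np.asarray(sigma, dtype=float) - b) / a


def error_metrics(
    delta_calc: np.ndarray,
    delta_exp: np.ndarray,
    labels: Sequence[str],
) -> ErrorMetrics:
    """Residual statistics of predicted vs experimental shifts.

    Errors e = δ_calc − δ_exp; SDE uses the sample (n−1) denominator; the
    worst nucleus is reported by label alongside MaxAE.
    """
    delta_calc = np.asarray(delta_calc, dtype=float)
    delta_exp = np.asarray(delta_exp, dtype=float)
    if len(delta_calc) == 0:
        raise StatsError("empty input")
    if not (len(delta_calc) == len(delta_exp) == len(labels)):
        raise StatsError("length mismatch between shifts and labels")
    e = delta_calc - delta_exp
    worst = int(np.argmax(np.abs(e)))
    return ErrorMetrics(
        mae=float(np.mean(np.abs(e))),
        maxae=float(np.abs(e[worst])),
        maxae_label=str(labels[worst]),
        sde=float(np.std(e, ddof=1)) if len(e) > 1 else 0.0,
        mse=float(np.mean(e)),
    )


def _matched(
    sigma: ShieldingTable, exp: ExperimentalShifts, method: str | None
) -> pd.DataFrame:
    f = sigma.frame
    if method is not None:
        f = f[f["method"] == method]
        if f.empty:
            raise StatsError(f"no shieldings for method {method!r}")
    if f["method"].nunique() > 1:
        raise StatsError(
            f"shielding table mixes methods {sorted(f['method'].unique())}; "
            "pass method= to select one"
        )
    merged = f.merge(exp.frame, on=["system", "nucleus"], how="outer", indicator=True)
    orphans = merged[merged["_merge"] != "both"]
    if not orphans.empty:
        names = [
            f"{r.system}:{r.nucleus}" for r in orphans.itertuples()
        ]
        raise StatsError(f"unmatched nuclei between shieldings and shifts: {names}")
    return merged.drop(columns="_merge")


def fit_shieldings(
    sigma: ShieldingTable,
    exp: ExperimentalShifts,
    method: str | None = None,
) -> RegressionReport:
    """OLS fit σ = aδ_exp + b and residual statistics of the inverted shifts.

    Pairs are matched by (system, nucleus); any unmatched nucleus on
    either side is an error.  R² is the coefficient of determination of
    the σ-on-δ fit; the error metrics are computed from the predicted
    shifts on the same pairs.
    """
    m = _matched(sigma, exp, method)
    if len(m) < 3:
        raise StatsError(f"regression needs >= 3 matched pairs, got {len(m)}")
    delta = m["delta_exp_ppm"].to_numpy(dtype=float)
    sig = m["sigma_ppm"].to_numpy(dtype=float)
    res = sps.linregress(delta, sig)
    a, b = float(res.slope), float(res.intercept)
    dcalc = predict_shifts(sig, a, b)
    labels = [f"{r.nucleus}({r.system})" for r in m.itertuples()]
    em = error_metrics(dcalc, delta, labels)
    return RegressionReport(
        a=a,
        b=b,
        r2=float(res.rvalue**2),
        mae=em.mae,
        maxae=em.maxae,
        maxae_label=em.maxae_label,
        sde=em.sde,
        mse=em.mse,
        n=len(m),
        method=str(m["method"].iloc[0]),
    )


def reference_shifts(sigma: ShieldingTable, sigma_ref: float) -> pd.DataFrame:
    """Absolute referencing against a computed standard: δ = σ_ref − σ."""
    if not np.isfinite(sigma_ref):
        raise StatsError("reference shielding must be finite")
    out = sigma.frame.copy()
    out["delta_calc_ppm"] = sigma_ref - out["sigma_ppm"]
    return out.drop(columns="sigma_ppm")


def _aligned(base: ShieldingTable, other: ShieldingTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    key = ["system", "nucleus"]
    b = base.frame.set_index(key).sort_index()
    o = other.frame.set_index(key).sort_index()
    if not b.index.equals(o.index):
        only_b = b.index.difference(o.index).tolist()
        only_o = o.index.difference(b.index).tolist()
        raise StatsError(f"nucleus mismatch: only-base {only_b}, only-other {only_o}")
    return b, o


def apply_correction(
    base: ShieldingTable, delta: ShieldingTable, method: str | None = None
) -> ShieldingTable:
    """Additive per-nucleus correction σ' = σ + Δσ (strict label matching).

    Used identically for molecular higher-level corrections, spin–orbit
    corrections supplied externally, and the MD vibrational correction.
    """
    b, d = _aligned(base, delta)
    out = b.copy()
    out["sigma_ppm"] = b["sigma_ppm"] + d["sigma_ppm"]
    if method is not None:
        out["method"] = method
    return ShieldingTable(out.reset_index())


def average_tables(t1: ShieldingTable, t2: ShieldingTable) -> ShieldingTable:
    """Per-nucleus mean of two shielding tables (e.g. two crystallographic
    orientations of the same labile proton)."""
    a, b = _aligned(t1, t2)
    out = a.copy()
    out["sigma_ppm"] = (a["sigma_ppm"] + b["sigma_ppm"]) / 2.0
    return ShieldingTable(out.reset_index())


# ---------------------------------------------------------------------------
# Table reproduction


def report_tables(
    sigma: ShieldingTable,
    exp: ExperimentalShifts,
    methods: Sequence[str] | None = None,
) -> pd.DataFrame:
    """One regression report per method, as a DataFrame in table layout."""
    methods = list(methods) if methods is not None else sigma.methods
    rows = []
    for m in methods:
        r = fit_shieldings(sigma, exp, method=m)
        rows.append(
            {
                "method": m,
                "slope": r.a,
                "intercept": r.b,
                "r2": r.r2,
                "mae": r.mae,
                "maxae": r.maxae,
                "maxae_label": r.maxae_label,
                "sde": r.sde,
                "mse": r.mse,
                "n": r.n,
            }
        )
    return pd.DataFrame(rows)


def round_half_even(x: float, decimals: int) -> float:
    """Round at display precision with the half-even tie rule."""
    return float(np.round(x, decimals))


def render_report(reports: pd.DataFrame) -> str:
    """Format regression reports the way correlation tables are printed:
    slope/intercept/MAE/MaxAE/SDE at 2 decimals, R² at 4."""
    lines = [
        f"{'method':<22s} {'slope':>6s} {'intercept':>9s} {'R2':>7s} "
        f"{'MAE':>5s} {'MaxAE':>5s} {'':<12s} {'SDE':>5s}"
    ]
    for r in reports.itertuples():
        lines.append(
            f"{r.method:<22s} {round_half_even(r.slope, 2):>6.2f} "
            f"{round_half_even(r.intercept, 2):>9.2f} "
            f"{round_half_even(r.r2, 4):>7.4f} "
            f"{round_half_even(r.mae, 2):>5.2f} "
            f"{round_half_even(r.maxae, 2):>5.2f} {r.maxae_label:<12s} "
            f"{round_half_even(r.sde, 2):>5.2f}"
        )
    return "\n".join(lines)
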