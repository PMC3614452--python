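"""Evaluation quantities: goodness of fit, conductance, coverage volumes.

The treatment-planning surrogate for electrochemotherapy success is the
coverage volume: the fraction of a target region whose local field magnitude
exceeds the reversible (drug uptake) or irreversible (ablation) threshold.
With P1 elements the field is constant per element, so elements are
classified whole (the source of small staircase effects in coverage curves).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .fem import FieldSolution
from .solvers import IVCurve


class MetricError(ValueError):
    pass


# ---------------------------------------------------------------------------
# coefficient of determination
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitStatistics:
    """R^2 = 1 - SS_err/SS_tot between measured y_i and modelled f_i."""

    r2: float
    ss_err: float
    ss_tot: float
    n: int
    y_mean: float

    def to_dict(self) -> dict:
        return {
            "R2": self.r2, "SS_err": self.ss_err, "SS_tot": self.ss_tot,
            "n": self.n, "y_mean": self.y_mean,
        }


def r_squared(measured, modelled) -> FitStatistics:
    """Goodness of fit of modelled values against measurements.

    R^2 = 1 means a perfect fit; values near zero or negative mean the model
    does no better (or worse) than the mean of the measurements.
    """
    y = np.asarray(measured, dtype=float)
    f = np.asarray(modelled, dtype=float)
    if y.shape != f.shape or y.ndim != 1 or len(y) < 2:
        raise MetricError("measured and modelled must be equal-length 1-D, n >= 2")
    y_mean = float(y.mean())
    ss_err = float(np.sum((y - f) ** 2))
    ss_tot = float(np.sum((y - y_mean) ** 2))
    if ss_tot == 0.0:
        raise MetricError("all measured values identical: R^2 undefined (SS_tot = 0)")
    return FitStatistics(
        r2=1.0 - ss_err / ss_tot, ss_err=ss_err, ss_tot=ss_tot,
        n=len(y), y_mean=y_mean,
    )


# ---------------------------------------------------------------------------
# conductance
# ---------------------------------------------------------------------------

def conductance_curve(iv: IVCurve) -> pd.DataFrame:
    """G(U) = I/U per sweep point (columns U_V, G_S); U = 0 rows excluded.

    A falling conductance under a non-decreasing sigma(E) indicates a solver
    problem, so non-monotonic G triggers a warning.
    """
    U, I = iv.U, iv.I
    keep = U > 0
    if not np.all(keep):
        warnings.warn("U = 0 points excluded from the conductance curve")
    U, I = U[keep], I[keep]
    G = I / U
    if np.any(np.diff(G) < -1e-9 * np.abs(G[:-1])):
        warnings.warn("conductance G(U) is not monotone non-decreasing")
    return pd.DataFrame({"U_V": U, "G_S": G})


# ---------------------------------------------------------------------------
# coverage volumes
# ---------------------------------------------------------------------------

def volume_fraction_above(solution: FieldSolution, region: str,
                          threshold_vcm: float) -> float:
    """Volume percentage of ``region`` with |E| >= ``threshold_vcm`` [V/cm]."""
    if threshold_vcm <= 0:
        raise MetricError("threshold must be > 0")
    mesh = solution.mesh
    mask = mesh.region_mask(region)
    if not np.any(mask):
        raise MetricError(f"region {region!r} has no elements")
    vols = mesh.tet_volumes()[mask]
    above = solution.E_mag_vcm[mask] >= threshold_vcm
    return float(100.0 * vols[above].sum() / vols.sum())


NOT_REACHED = None  # sentinel for "100% coverage not reached in sweep"


@dataclass
class CoverageCurve:
    """Per (region, threshold) coverage V% as a function of applied voltage."""

    table: pd.DataFrame  # columns: region, threshold_V_per_cm, U_V, V_percent

    def select(self, region: str, threshold_vcm: float) -> pd.DataFrame:
        t = self.table
        out = t[(t.region == region) & (t.threshold_V_per_cm == threshold_vcm)]
        if out.empty:
            raise MetricError(
                f"no coverage entries for {region!r} at {threshold_vcm} V/cm"
            )
        return out.sort_values("U_V")

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def coverage_curve(solutions: Sequence[FieldSolution],
                   thresholds: Dict[str, Sequence[float]]) -> CoverageCurve:
    """Coverage over a voltage sweep.

    ``thresholds`` maps region name -> threshold list in V/cm (typically
    ``[E_rev, E_irrev]`` of that tissue).
    """
    rows = []
    for sol in solutions:
        for region, ths in thresholds.items():
            for th in ths:
                rows.append(
                    {
                        "region": region,
                        "threshold_V_per_cm": float(th),
                        "U_V": sol.U,
                        "V_percent": volume_fraction_above(sol, region, th),
                    }
                )
    return CoverageCurve(table=pd.DataFrame(rows))


def min_voltage_full_coverage(curve: CoverageCurve, region: str,
                              threshold_vcm: float,
                              tol: float = 1e-9) -> Optional[float]:
    """Smallest swept voltage with 100% coverage, or ``None`` if not reached."""
    sel = curve.select(region, threshold_vcm)
    full = sel[sel.V_percent >= 100.0 - tol]
    if full.empty:
        return NOT_REACHED
    return float(full.U_V.min())
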