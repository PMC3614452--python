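"""Inverse identification of sigma(E) parameters from current-voltage data.

Given measurements (U_j, I_j) of end-of-pulse electrode current, the
parameters theta of a conductivity family (sigma0, k_sigma for the linear
law; sigma0, c1, c2 for the exponential law) are identified by minimizing
the sum-of-squares misfit

    f(theta) = sum_j (I_FEM(U_j; theta) - I_j)^2

with bound-constrained Gauss-Newton (trust-region reflective least squares)
and multistart.  The model sensitivities dI_FEM/dtheta are computed by
direct differentiation of the discrete residual: at each converged forward
state one extra linear solve with the (already assembled) consistent tangent
yields the adjoint weights, after which every parameter costs one
matrix-free residual-derivative evaluation.  Central finite differences are
retained as a validation oracle (``sensitivity="finite_difference"``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse.linalg as spla
from scipy.optimize import least_squares

from .conductivity import ConductivityModel, single_tissue_registry
from .datasets import IVDataset
from .fem import full_newton_tangent, solve_fixed_sigma, stiffness_action
from .geometry import Mesh
from .metrics import r_squared
from .solvers import SolverSettings, dsigma_elem, solve_npa
from .units import V_PER_CM

FAMILY_PARAMS = {
    "constant": ("sigma0",),
    "linear": ("sigma0", "k_sigma"),
    "exponential": ("sigma0", "c1", "c2"),
}

PARAM_UNITS = {
    "sigma0": "S/m",
    "k_sigma": "S/m per V/cm",
    "c1": "S/m",
    "c2": "cm/V",
}


class InverseError(RuntimeError):
    pass


def make_model(family: str, theta: np.ndarray) -> ConductivityModel:
    names = FAMILY_PARAMS[family]
    kw = dict(zip(names, np.asarray(theta, dtype=float)))
    return ConductivityModel(family=family, **kw)


def _dsigma_dtheta(family: str, e_vcm: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Partial derivatives of sigma w.r.t. each parameter at fixed field.

    Shape (n_params, n_elements); units S/m per parameter unit."""
    if family == "constant":
        return np.ones((1, len(e_vcm)))
    if family == "linear":
        return np.stack([np.ones_like(e_vcm), e_vcm])
    if family == "exponential":
        _, c1, c2 = theta
        return np.stack(
            [
                np.ones_like(e_vcm),
                np.expm1(c2 * e_vcm),
                c1 * e_vcm * np.exp(c2 * e_vcm),
            ]
        )
    raise InverseError(f"family {family!r} is not fittable")


class SingleTissueForward:
    """Forward current model I_FEM(U; theta) on a single-tissue mesh."""

    def __init__(self, mesh: Mesh, family: str,
                 settings: SolverSettings = SolverSettings()):
        if len(mesh.region_names) != 1:
            raise InverseError("inverse analysis expects a single-tissue mesh")
        if family not in FAMILY_PARAMS:
            raise InverseError(
                f"family must be one of {sorted(FAMILY_PARAMS)}, got {family!r}"
            )
        self.mesh = mesh
        self.family = family
        self.tissue = mesh.region_names[0]
        self.settings = settings
        self._anode = mesh.electrode_nodes("anode")
        self._free: Optional[np.ndarray] = None

    @property
    def n_params(self) -> int:
        return len(FAMILY_PARAMS[self.family])

    def unit_conductance(self) -> float:
        """Geometry cell factor: current at U = 1 V with sigma = 1 S/m."""
        sol = solve_fixed_sigma(
            self.mesh, np.ones(self.mesh.n_elements), 1.0
        )
        return sol.I

    def registry(self, theta):
        return single_tissue_registry(self.tissue, make_model(self.family, theta))

    def _solutions(self, theta, U_list):
        """One solution per entry of ``U_list`` (replicates share a solve)."""
        reg = self.registry(theta)
        uniq, inverse = np.unique(np.asarray(U_list, dtype=float),
                                  return_inverse=True)
        state: dict = {}
        per_uniq = [
            solve_npa(self.mesh, reg, float(u), self.settings, _state=state)
            for u in uniq
        ]
        return [per_uniq[i] for i in inverse]

    def currents(self, theta, U_list) -> np.ndarray:
        return np.array([s.I for s in self._solutions(theta, U_list)])

    def currents_and_jac(self, theta, U_list) -> Tuple[np.ndarray, np.ndarray]:
        """Currents and dI/dtheta via the direct/adjoint sensitivity method."""
        mesh = self.mesh
        reg = self.registry(theta)
        if self._free is None:
            fixed = np.union1d(self._anode, mesh.electrode_nodes("cathode"))
            self._free = np.setdiff1d(np.arange(mesh.n_nodes), fixed)
        free = self._free
        sols = self._solutions(theta, U_list)
        I = np.array([s.I for s in sols])
        J = np.empty((len(sols), self.n_params))
        ind = np.zeros(mesh.n_nodes)
        ind[self._anode] = 1.0
        cache: Dict[int, np.ndarray] = {}
        for row, sol in enumerate(sols):
            key = id(sol)  # replicate voltages share the same solution
            if key not in cache:
                ds = dsigma_elem(mesh, reg, sol.E)
                Kt = full_newton_tangent(mesh, sol.sigma_elem, ds, sol.E)
                rhs = (Kt @ ind)[free]
                w = spla.spsolve(Kt[free][:, free].tocsc(), rhs)
                dsig = _dsigma_dtheta(self.family, sol.E_mag_vcm, theta)
                grad = np.empty(self.n_params)
                for p in range(self.n_params):
                    v = stiffness_action(mesh, dsig[p], sol.phi)
                    grad[p] = v[self._anode].sum() - w @ v[free]
                cache[key] = grad
            J[row] = cache[key]
        return I, J

    def currents_and_jac_fd(self, theta, U_list,
                            rel_step: float = 1e-6) -> Tuple[np.ndarray, np.ndarray]:
        """Finite-difference sensitivities (validation oracle)."""
        theta = np.asarray(theta, dtype=float)
        I0 = self.currents(theta, U_list)
        J = np.empty((len(I0), len(theta)))
        for p in range(len(theta)):
            h = rel_step * max(abs(theta[p]), 1e-8)
            tp, tm = theta.copy(), theta.copy()
            tp[p] += h
            tm[p] = max(tm[p] - h, 0.0)
            J[:, p] = (self.currents(tp, U_list) - self.currents(tm, U_list)) / (
                tp[p] - tm[p]
            )
        return I0, J


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitSpec:
    """Inverse-analysis configuration.

    ``family`` selects the sigma(E) law; initial guesses and bounds default
    to data-driven values (sigma0 from the lowest-voltage secant divided by
    the geometry cell factor, slope parameters starting just above zero) and
    can be overridden per parameter.
    """

    family: str = "linear"
    x0: Optional[Dict[str, float]] = None
    bounds: Optional[Dict[str, Tuple[float, float]]] = None
    sensitivity: str = "direct"   # direct | finite_difference
    multistart: int = 5
    ftol: float = 1e-12
    xtol: float = 1e-12

    def __post_init__(self):
        if self.family not in FAMILY_PARAMS:
            raise InverseError(f"unknown family {self.family!r}")
        if self.sensitivity not in ("direct", "finite_difference"):
            raise InverseError(f"unknown sensitivity {self.sensitivity!r}")
        if self.multistart < 1:
            raise InverseError("multistart must be >= 1")


@dataclass
class InverseResult:
    """Fit output: parameters (with units), objective, residuals, R^2."""

    family: str
    params: Dict[str, float]
    units: Dict[str, str]
    objective: float
    residuals: np.ndarray
    r2: float
    gradient_norm: float
    n_starts: int
    trace: List[dict]

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "params": self.params,
            "units": self.units,
            "objective_A2": self.objective,
            "R2": self.r2,
            "gradient_norm": self.gradient_norm,
            "n_starts": self.n_starts,
        }


def objective(theta, forward: SingleTissueForward,
              data: IVDataset) -> Tuple[float, np.ndarray]:
    """Sum-of-squares misfit f and its gradient at ``theta``."""
    I, J = forward.currents_and_jac(theta, data.U)
    r = I - data.I
    return float(r @ r), 2.0 * (J.T @ r)


def _default_setup(spec: FitSpec, forward: SingleTissueForward,
                   data: IVDataset):
    g_unit = forward.unit_conductance()
    j = int(np.argmin(data.U))
    sigma0_init = (data.I[j] / data.U[j]) / g_unit
    # field scale from a baseline solve at the largest voltage
    sol = solve_fixed_sigma(
        forward.mesh, np.full(forward.mesh.n_elements, sigma0_init),
        float(data.U.max()),
    )
    e_ref = float(np.quantile(sol.E_mag_vcm, 0.9))
    defaults_x0 = {
        "sigma0": sigma0_init,
        "k_sigma": 0.05 * sigma0_init / e_ref,
        "c1": 0.05 * sigma0_init,
        "c2": 0.5 / e_ref,
    }
    defaults_bounds = {
        "sigma0": (sigma0_init / 20.0, sigma0_init * 20.0),
        "k_sigma": (0.0, 20.0 * sigma0_init / e_ref),
        "c1": (0.0, 20.0 * sigma0_init),
        "c2": (0.0, 20.0 / e_ref),
    }
    names = FAMILY_PARAMS[spec.family]
    x0 = np.array([
        (spec.x0 or {}).get(nm, defaults_x0[nm]) for nm in names
    ])
    lo = np.array([
        (spec.bounds or {}).get(nm, defaults_bounds[nm])[0] for nm in names
    ])
    hi = np.array([
        (spec.bounds or {}).get(nm, defaults_bounds[nm])[1] for nm in names
    ])
    return x0, lo, hi


def fit_sigma_model(spec: FitSpec, forward: SingleTissueForward,
                    data: IVDataset) -> InverseResult:
    """Bounded Gauss-Newton minimization of the misfit, with multistart."""
    names = FAMILY_PARAMS[spec.family]
    if len(np.unique(data.U)) < len(names) + 1:
        raise InverseError(
            f"need at least {len(names) + 1} distinct voltages to fit "
            f"{spec.family} ({len(np.unique(data.U))} given)"
        )
    x0, lo, hi = _default_setup(spec, forward, data)

    use_fd = spec.sensitivity == "finite_difference"

    def residuals(theta):
        return forward.currents(theta, data.U) - data.I

    def jac(theta):
        if use_fd:
            return forward.currents_and_jac_fd(theta, data.U)[1]
        return forward.currents_and_jac(theta, data.U)[1]

    rng = np.random.default_rng(12345)  # deterministic multistart pattern
    starts = [x0]
    while len(starts) < spec.multistart:
        factors = np.exp(rng.uniform(-1.2, 1.2, size=len(x0)))
        starts.append(np.clip(x0 * factors, lo + 1e-300, hi))

    best = None
    trace = []
    for s0 in starts:
        try:
            res = least_squares(
                residuals, s0, jac=jac, bounds=(lo, hi),
                ftol=spec.ftol, xtol=spec.xtol, x_scale=np.maximum(x0, 1e-12),
            )
        except Exception as exc:
            trace.append({"x0": s0.tolist(), "error": str(exc)})
            continue
        trace.append({"x0": s0.tolist(), "cost": float(res.cost),
                      "nfev": int(res.nfev), "x": res.x.tolist()})
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise InverseError("every optimizer start failed")

    theta = best.x
    r = best.fun
    I_model = r + data.I
    grad = 2.0 * (jac(theta).T @ r)
    return InverseResult(
        family=spec.family,
        params=dict(zip(names, map(float, theta))),
        units={nm: PARAM_UNITS[nm] for nm in names},
        objective=float(r @ r),
        residuals=r,
        r2=r_squared(data.I, I_model).r2,
        gradient_norm=float(np.linalg.norm(grad)),
        n_starts=len(starts),
        trace=trace,
    )


# ---------------------------------------------------------------------------
# identifiability diagnostics
# ---------------------------------------------------------------------------

def identifiability_report(forward: SingleTissueForward, data: IVDataset,
                           result: InverseResult,
                           corr_limit: float = 0.99) -> dict:
    """Condition and correlation diagnostics of the sensitivity matrix.

    Flags a parameter as practically non-identifiable when its scaled
    sensitivity column is negligible (e.g. a slope that fitted to ~0 on data
    never leaving the linear regime) or when two columns are correlated
    beyond ``corr_limit`` (e.g. c1/c2 of an exponential fit to linear-truth
    data).
    """
    names = FAMILY_PARAMS[result.family]
    theta = np.array([result.params[nm] for nm in names])
    _, S = forward.currents_and_jac(theta, data.U)
    scaled = S * theta[None, :]          # sensitivity to relative change
    i_scale = float(np.linalg.norm(data.I))
    col_norm = np.linalg.norm(scaled, axis=0) / max(i_scale, 1e-300)
    # a parameter whose relative sensitivity is below 1e-4 moves the
    # predicted currents by less than measurement noise ever could
    insensitive = col_norm < 1e-4

    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.linalg.norm(S, axis=0)
        Sn = S / np.where(denom > 0, denom, 1.0)
        corr = Sn.T @ Sn
    flagged_pairs = []
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            if abs(corr[a, b]) > corr_limit:
                flagged_pairs.append((names[a], names[b], float(corr[a, b])))

    nonzero = col_norm > 0
    cond = float(np.linalg.cond(scaled[:, nonzero])) if nonzero.any() else np.inf
    non_identifiable = sorted(
        {names[i] for i in np.flatnonzero(insensitive)}
        | {nm for pair in flagged_pairs for nm in pair[:2]}
    )
    if non_identifiable:
        warnings.warn(
            f"practically non-identifiable parameters: {non_identifiable}"
        )
    return {
        "condition_number": cond,
        "relative_column_norms": dict(zip(names, map(float, col_norm))),
        "correlation": corr.tolist(),
        "correlated_pairs": flagged_pairs,
        "non_identifiable": non_identifiable,
    }
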