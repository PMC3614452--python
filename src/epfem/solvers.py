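"""Forward strategies for the field-dependent conductivity problem.

Two strategies are provided for sigma = sigma(|E|):

NPA (nonlinear parametric analysis)
    Damped Newton iteration on the nonlinear residual, wrapped in a
    parametric continuation loop that raises the applied voltage from 0 to
    the target in adaptive steps, reusing each converged potential as the
    next initial guess.  The Newton tangent is either the consistent
    Jacobian (``full_newton``, isotropic tissues) or the lagged-conductivity
    fixed-point map (``picard``, always available); both are damped by
    halving the step while the nonlinear residual grows.

SA (sequential analysis)
    A discrete sequence of static solves emulating progressive
    permeabilization during the pulse: step 0 uses baseline conductivities,
    step k re-evaluates sigma per element from step k-1's field through a
    quantized (step-function) version of sigma(E).  Conductivity can only
    increase across the sequence (permeabilization is not undone within a
    pulse); the ratchet can be disabled for plain fixed-point iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.sparse.linalg as spla

from .conductivity import TissueRegistry
from .fem import (
    FieldSolution,
    dirichlet_system,
    element_field,
    full_newton_tangent,
    reaction_currents,
    solve_fixed_sigma,
    stiffness_action,
)
from .geometry import Mesh
from .units import V_PER_CM


class SolverNonConvergence(RuntimeError):
    """Continuation stalled; carries the last converged voltage."""

    def __init__(self, msg, last_converged_U=None, last_solution=None):
        super().__init__(msg)
        self.last_converged_U = last_converged_U
        self.last_solution = last_solution


@dataclass(frozen=True)
class SolverSettings:
    """Damped-Newton and continuation controls.

    ``newton_tol`` is the relative nonlinear-residual tolerance (free-node
    residual norm over the reaction-force norm); damping halves the step on
    residual growth down to ``lambda_min``; continuation starts at
    ``du_init_frac * U_target`` and grows/shrinks by the given factors.
    """

    newton_tol: float = 1e-8
    abs_tol: float = 1e-14
    max_newton_iter: int = 40
    lambda_min: float = 2.0 ** -10
    scheme: str = "auto"          # auto | full_newton | picard
    du_init_frac: float = 1.0 / 20.0
    grow: float = 1.5
    shrink: float = 0.5
    fast_iters: int = 3

    def __post_init__(self):
        if not (0 < self.lambda_min <= 1):
            raise ValueError("lambda_min must be in (0, 1]")
        if self.newton_tol <= 0:
            raise ValueError("newton_tol must be > 0")
        if self.scheme not in ("auto", "full_newton", "picard"):
            raise ValueError(f"unknown scheme {self.scheme!r}")


@dataclass(frozen=True)
class SAConfig:
    """Sequential-analysis controls.

    ``n_steps`` static solves follow the baseline solve; sigma(E) is
    quantized onto ``levels`` equal conductivity steps (``use_quantized``
    False uses the smooth law).  The raw update sigma_k = f(E_{k-1}) is a
    fixed-point iteration that can flip a whole near-uniform region between
    its permeabilized and unpermeabilized states on steep step laws; with
    ``adaptive`` the update weight is halved whenever successive updates
    reverse direction, which restores convergence toward the self-consistent
    state without changing the converged value.  ``ratchet`` forbids any
    per-element conductivity decrease across the sequence (permeabilization
    treated as irreversible within the pulse)."""

    n_steps: int = 5
    levels: int = 5
    use_quantized: bool = True
    ratchet: bool = False
    adaptive: bool = True

    def __post_init__(self):
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.levels < 2:
            raise ValueError("levels must be >= 2")


@dataclass
class IVPoint:
    U: float
    I: float
    converged: bool
    iterations: int


@dataclass
class IVCurve:
    """Current-voltage relationship I(U) with convergence bookkeeping."""

    points: List[IVPoint] = field(default_factory=list)

    @property
    def U(self) -> np.ndarray:
        return np.array([p.U for p in self.points])

    @property
    def I(self) -> np.ndarray:
        return np.array([p.I for p in self.points])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "U_V": self.U,
                "I_A": self.I,
                "iters": [p.iterations for p in self.points],
                "converged": [p.converged for p in self.points],
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# per-element conductivity evaluation
# ---------------------------------------------------------------------------

def _region_props(mesh: Mesh, registry: TissueRegistry):
    return [(mesh.region_mask(nm), registry[nm]) for nm in mesh.region_names]


def _is_isotropic(mesh: Mesh, registry: TissueRegistry) -> bool:
    return all(registry[nm].isotropic for nm in mesh.region_names)


def principal_sigma_elem(mesh: Mesh, registry: TissueRegistry,
                         E_vm: np.ndarray) -> np.ndarray:
    """Per-element per-principal-axis sigma(|E|), shape (m, 3)."""
    emag_vcm = np.linalg.norm(E_vm, axis=1) / V_PER_CM
    out = np.empty((mesh.n_elements, 3))
    for mask, props in _region_props(mesh, registry):
        if not np.any(mask):
            continue
        out[mask] = props.principal_sigmas(emag_vcm[mask])
    return out


def sigma_elem_from_principal(mesh: Mesh, registry: TissueRegistry,
                              principal: np.ndarray) -> np.ndarray:
    """(m,) scalars if every tissue is isotropic, else lab-frame (m,3,3)."""
    if _is_isotropic(mesh, registry):
        return principal[:, 0].copy()
    out = np.zeros((mesh.n_elements, 3, 3))
    for mask, props in _region_props(mesh, registry):
        if not np.any(mask):
            continue
        F = props.fiber_frame
        diag = np.zeros((int(mask.sum()), 3, 3))
        idx = np.arange(3)
        diag[:, idx, idx] = principal[mask]
        out[mask] = np.einsum("ai,nab,bj->nij", F, diag, F)
    return out


def evaluate_sigma_elem(mesh: Mesh, registry: TissueRegistry,
                        E_vm: np.ndarray) -> np.ndarray:
    return sigma_elem_from_principal(
        mesh, registry, principal_sigma_elem(mesh, registry, E_vm)
    )


def baseline_sigma_elem(mesh: Mesh, registry: TissueRegistry) -> np.ndarray:
    return evaluate_sigma_elem(mesh, registry, np.zeros((mesh.n_elements, 3)))


def dsigma_elem(mesh: Mesh, registry: TissueRegistry,
                E_vm: np.ndarray) -> np.ndarray:
    """Per-element d sigma/dE (S/m per V/cm): (m,) scalars for isotropic
    meshes, lab-frame (m,3,3) per-axis slope tensors otherwise."""
    emag_vcm = np.linalg.norm(E_vm, axis=1) / V_PER_CM
    principal = np.empty((mesh.n_elements, 3))
    for mask, props in _region_props(mesh, registry):
        if not np.any(mask):
            continue
        principal[mask] = np.stack(
            [m.dsigma_dE(emag_vcm[mask]) for m in props.models], axis=-1
        )
    return sigma_elem_from_principal(mesh, registry, principal)


# ---------------------------------------------------------------------------
# nonlinear stationary solve (one voltage)
# ---------------------------------------------------------------------------

def _residual(mesh, registry, phi, free) -> Tuple[np.ndarray, float, np.ndarray]:
    E = element_field(mesh, phi)
    sig = evaluate_sigma_elem(mesh, registry, E)
    r = stiffness_action(mesh, sig, phi)
    fixed_mask = np.ones(mesh.n_nodes, dtype=bool)
    fixed_mask[free] = False
    scale = np.linalg.norm(r[fixed_mask])
    rel = np.linalg.norm(r[free]) / max(scale, 1e-300)
    return r, rel, sig


def _nonlinear_solve(mesh: Mesh, registry: TissueRegistry, U: float,
                     settings: SolverSettings,
                     phi0: Optional[np.ndarray]) -> Tuple[FieldSolution, int]:
    """Damped Newton/Picard at fixed applied voltage; raises on failure."""
    scheme = settings.scheme
    if scheme == "auto":
        scheme = "full_newton"

    sigma0 = baseline_sigma_elem(mesh, registry)
    sys0 = dirichlet_system(mesh, sigma0, {"anode": U, "cathode": 0.0})
    free = sys0.free
    phi = phi0.copy() if phi0 is not None else sys0.solve()
    # pin the Dirichlet values of the initial guess to the current voltage
    phi[sys0.fixed] = sys0.fixed_values

    r, rel, sig = _residual(mesh, registry, phi, free)
    abs0 = np.linalg.norm(r[free])
    for it in range(1, settings.max_newton_iter + 1):
        if rel <= settings.newton_tol or abs0 <= settings.abs_tol:
            E = element_field(mesh, phi)
            currents = reaction_currents(mesh, sig, phi)
            return (
                FieldSolution(mesh=mesh, phi=phi, E=E, sigma_elem=sig, U=U,
                              currents=currents),
                it - 1,
            )
        if scheme == "picard":
            sysl = dirichlet_system(mesh, sig, {"anode": U, "cathode": 0.0})
            dphi = sysl.solve() - phi
        else:
            E = element_field(mesh, phi)
            ds = dsigma_elem(mesh, registry, E)
            J = full_newton_tangent(mesh, sig, ds, E)
            Jff = J[free][:, free].tocsc()
            dphi = np.zeros_like(phi)
            dphi[free] = spla.spsolve(Jff, -r[free])
        lam = 1.0
        while True:
            trial = phi + lam * dphi
            r_t, rel_t, sig_t = _residual(mesh, registry, trial, free)
            if rel_t < rel or rel_t <= settings.newton_tol:
                phi, r, rel, sig = trial, r_t, rel_t, sig_t
                abs0 = np.linalg.norm(r[free])
                break
            lam *= 0.5
            if lam < settings.lambda_min:
                raise SolverNonConvergence(
                    f"damping underflow at U={U:g} V (residual {rel:.3e})"
                )
    raise SolverNonConvergence(
        f"no convergence in {settings.max_newton_iter} iterations at U={U:g} V "
        f"(residual {rel:.3e})"
    )


# ---------------------------------------------------------------------------
# NPA: parametric continuation over the applied voltage
# ---------------------------------------------------------------------------

def solve_npa(mesh: Mesh, registry: TissueRegistry, U_target: float,
              settings: SolverSettings = SolverSettings(),
              _state: Optional[dict] = None) -> FieldSolution:
    """Solve at ``U_target`` by continuation from 0 V (or a carried state).

    The internal ``_state`` dict (keys ``U``, ``phi``) lets voltage sweeps
    reuse the previous solution; :func:`iv_sweep` drives it.
    """
    if U_target < 0:
        raise ValueError("U_target must be >= 0")
    if U_target == 0.0:
        sig = baseline_sigma_elem(mesh, registry)
        return solve_fixed_sigma(mesh, sig, 0.0)

    state = _state if _state is not None else {}
    U_cur = state.get("U", 0.0)
    phi = state.get("phi")
    if U_cur > U_target:  # restart continuation for a lower target
        U_cur, phi = 0.0, None
    dU = state.get("dU", U_target * settings.du_init_frac)
    dU = min(dU, max(U_target - U_cur, 0.0)) or U_target * settings.du_init_frac

    last_sol = None
    total_iters = 0
    while U_cur < U_target - 1e-12 * U_target:
        U_next = min(U_cur + dU, U_target)
        guess = None
        if phi is not None:
            guess = phi * (U_next / U_cur) if U_cur > 0 else phi
        try:
            sol, iters = _nonlinear_solve(mesh, registry, U_next, settings, guess)
        except SolverNonConvergence:
            dU *= settings.shrink
            if dU < 1e-6 * U_target:
                raise SolverNonConvergence(
                    f"continuation stalled below U={U_next:g} V",
                    last_converged_U=U_cur,
                    last_solution=last_sol,
                )
            continue
        total_iters += iters
        U_cur, phi, last_sol = U_next, sol.phi, sol
        if iters <= settings.fast_iters:
            dU *= settings.grow
    if last_sol is None:  # state already at U_target (e.g. repeated call)
        last_sol, it = _nonlinear_solve(mesh, registry, U_target, settings, phi)
        total_iters += it
        phi = last_sol.phi
    state.update(U=U_cur, phi=phi, dU=dU)
    last_sol.iterations = total_iters
    return last_sol


def iv_sweep(mesh: Mesh, registry: TissueRegistry, U_list: Sequence[float],
             settings: SolverSettings = SolverSettings(),
             keep_solutions: bool = False):
    """I(U) over an increasing voltage list, reusing continuation state.

    Returns an :class:`IVCurve`; with ``keep_solutions`` also the list of
    :class:`~epfem.fem.FieldSolution` per voltage.  Nonconvergence at some
    voltage raises :class:`SolverNonConvergence` carrying partial results.
    """
    U_arr = np.asarray(U_list, dtype=float)
    if np.any(np.diff(U_arr) <= 0):
        raise ValueError("U_list must be strictly increasing")
    curve = IVCurve()
    sols = []
    state: dict = {}
    for U in U_arr:
        try:
            sol = solve_npa(mesh, registry, float(U), settings, _state=state)
        except SolverNonConvergence as exc:
            exc.partial_curve = curve
            raise
        curve.points.append(
            IVPoint(U=float(U), I=sol.I, converged=True,
                    iterations=getattr(sol, "iterations", 0))
        )
        if keep_solutions:
            sols.append(sol)
    return (curve, sols) if keep_solutions else curve


# ---------------------------------------------------------------------------
# SA: sequence of static solves
# ---------------------------------------------------------------------------

def _quantize_fraction(frac: np.ndarray, levels: int) -> np.ndarray:
    """Quantize a saturation fraction in [0, 1] onto ``levels`` equal steps."""
    q = np.round(frac * (levels - 1)) / (levels - 1)
    return np.clip(q, 0.0, 1.0)


def sa_sigma_principal(mesh: Mesh, registry: TissueRegistry, E_vm: np.ndarray,
                       cfg: SAConfig) -> np.ndarray:
    """Per-element per-axis sigma for the next SA step (Eq. sigma_k = f(E_{k-1})).

    Step-family conductivities are quantized onto ``cfg.levels`` equal-sigma
    levels between sigma0 and factor*sigma0; families without a saturation
    factor are used smoothly.
    """
    emag_vcm = np.linalg.norm(E_vm, axis=1) / V_PER_CM
    out = np.empty((mesh.n_elements, 3))
    for mask, props in _region_props(mesh, registry):
        if not np.any(mask):
            continue
        for ax, model in enumerate(props.models):
            s = model.sigma(emag_vcm[mask])
            if cfg.use_quantized and model.factor > 1.0:
                span = (model.factor - 1.0) * model.sigma0
                frac = (s - model.sigma0) / span
                s = model.sigma0 * (
                    1.0 + (model.factor - 1.0) * _quantize_fraction(frac, cfg.levels)
                )
            out[mask, ax] = s
    return out


def solve_sa(mesh: Mesh, registry: TissueRegistry, U: float,
             cfg: SAConfig = SAConfig()) -> List[FieldSolution]:
    """Sequential analysis: k+1 static solves with lagged conductivity.

    Returns the solutions for steps 0..k; currents I_0..I_k trace the
    modelled intra-pulse current rise.  With purely constant conductivities
    every step repeats step 0 (no electroporation, I = I_0).
    """
    principal = principal_sigma_elem(
        mesh, registry, np.zeros((mesh.n_elements, 3))
    )
    sols: List[FieldSolution] = []
    omega = 1.0
    prev_update: Optional[np.ndarray] = None
    for step in range(cfg.n_steps + 1):
        sig = sigma_elem_from_principal(mesh, registry, principal)
        sol = solve_fixed_sigma(mesh, sig, U)
        sols.append(sol)
        if step == cfg.n_steps:
            break
        target = sa_sigma_principal(mesh, registry, sol.E, cfg)
        update = target - principal
        if cfg.adaptive and prev_update is not None:
            if float(np.vdot(update, prev_update)) < 0:  # direction reversed
                omega = max(omega * 0.5, 1.0 / 64.0)
        step_vec = omega * update
        if cfg.ratchet:
            step_vec = np.maximum(step_vec, 0.0)
        principal = principal + step_vec
        prev_update = step_vec
    return sols


def sa_currents(sols: Sequence[FieldSolution]) -> np.ndarray:
    return np.array([s.I for s in sols])
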