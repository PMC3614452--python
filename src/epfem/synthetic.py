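"""Synthetic study inputs.

The in vivo current-voltage measurements behind the original experiments
(end-of-pulse currents under trains of eight 100 us pulses) are not publicly
deposited, so this module generates their stand-ins: currents from a
ground-truth forward model at a set of pulse amplitudes, corrupted by
multiplicative Gaussian measurement noise (relative SD ``noise_rel``,
default 3%, the standard instrumentation assumption).  Every dataset embeds
its seed and ground truth in the provenance sidecar so parameter-recovery
studies can score themselves.

It also provides the one-dimensional layered-slab oracle: for a stack of
tissue slabs in series the nonlinear problem reduces to a scalar
root-finding problem (the current density J is the same in every layer and
the per-layer fields must sum to the applied voltage), solved here by
bracketed root finding to near machine precision.  This is the independent
reference the 3-D nonlinear solvers are validated against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .conductivity import ConductivityModel
from .datasets import IVDataset
from .geometry import GeometryConfig, build_mesh
from .solvers import SolverSettings, iv_sweep
from .units import MM, V_PER_CM

CM2 = 1e-4  # m^2 per cm^2


# ---------------------------------------------------------------------------
# 1-D layered-slab oracle
# ---------------------------------------------------------------------------

def _invert_layer(model: ConductivityModel, J: float) -> float:
    """Field magnitude E [V/m] such that sigma(E) * E = J [A/m^2].

    sigma(E)*E is strictly increasing for non-decreasing sigma > 0, so the
    root is unique; the bracket is expanded geometrically.
    """
    if J == 0.0:
        return 0.0

    def g(e_vm):
        return model.sigma(e_vm / V_PER_CM) * e_vm - J

    # sigma >= sigma0 => root <= J/sigma0; widen slightly so rounding cannot
    # push g(hi) below zero when the root sits exactly at the bound
    hi = J / model.sigma0 * (1.0 + 1e-9)
    return brentq(g, 0.0, hi, xtol=1e-300, rtol=1e-15)


def slab_current(layers: Sequence[Tuple[ConductivityModel, float]],
                 area_cm2: float, U: float) -> float:
    """Exact series-stack current [A] at applied voltage ``U`` [V].

    ``layers`` are (sigma(E) model, thickness_mm) pairs; ``area_cm2`` the
    slab cross-section.  Solves sum_i E_i(J) t_i = U for the shared current
    density J, inverting J = sigma_i(E_i) E_i per layer by bracketed root
    finding.
    """
    if U == 0.0:
        return 0.0
    if U < 0:
        raise ValueError("U must be >= 0")
    t_m = np.array([t for _, t in layers]) * MM

    def voltage(J):
        return sum(
            _invert_layer(m, J) * t for (m, _), t in zip(layers, t_m)
        )

    # initial bracket guess; expanded geometrically below
    J_hi = U * max(m.sigma0 * max(m.factor, 1.0) for m, _ in layers) / t_m.sum()
    while voltage(J_hi) < U:
        J_hi *= 2.0
    J = brentq(lambda j: voltage(j) - U, 0.0, J_hi, xtol=1e-300, rtol=1e-15)
    resid = abs(voltage(J) - U)
    if resid > 1e-10 * U:
        raise RuntimeError(f"slab oracle root residual {resid:g} V at U={U:g}")
    return float(J * area_cm2 * CM2)


def generate_layered_slab_fixture(
    layers: Sequence[Tuple[ConductivityModel, float]],
    area_cm2: float,
    U_list: Sequence[float],
) -> pd.DataFrame:
    """Analytic I(U) table for a series slab stack (columns U_V, I_A)."""
    U = np.asarray(U_list, dtype=float)
    I = np.array([slab_current(layers, area_cm2, u) for u in U])
    return pd.DataFrame({"U_V": U, "I_A": I})


# ---------------------------------------------------------------------------
# synthetic I(U) datasets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticSpec:
    """Design of a synthetic current-voltage experiment.

    Defaults mirror the measurement campaigns the models are meant for:
    10 pulse amplitudes, geometrically spaced so the induced fields span the
    sub-threshold (conductivity ~ sigma0) through supra-threshold regime,
    three replicate measurements per amplitude (in vivo currents are
    measured in several animals per amplitude), and 3% relative
    multiplicative Gaussian noise.
    """

    truth: ConductivityModel
    geometry: GeometryConfig = field(
        default_factory=lambda: GeometryConfig(case="plate_single")
    )
    U_levels: Tuple[float, ...] = tuple(np.geomspace(20.0, 600.0, 10))
    replicates: int = 3
    noise_rel: float = 0.03
    seed: int = 0

    def __post_init__(self):
        if self.noise_rel < 0:
            raise ValueError("noise_rel must be >= 0")
        if any(u <= 0 for u in self.U_levels):
            raise ValueError("U levels must be positive")


def generate_iv_dataset(spec: SyntheticSpec, mesh=None) -> IVDataset:
    """Forward-model currents at the design voltages plus measurement noise.

    I_j = I_FEM(U_j; truth) * (1 + eps * z_j) with fixed-seed standard-normal
    z_j; non-positive draws are resampled.  The ground truth, design and
    seed are embedded in the dataset provenance.
    """
    from .conductivity import single_tissue_registry

    if mesh is None:
        mesh = build_mesh(spec.geometry)
    tissue = mesh.region_names[0]
    registry = single_tissue_registry(tissue, spec.truth)
    U = np.sort(np.asarray(spec.U_levels, dtype=float))
    curve = iv_sweep(mesh, registry, U, SolverSettings())
    I_clean = np.repeat(curve.I, spec.replicates)
    U_all = np.repeat(U, spec.replicates)

    rng = np.random.default_rng(spec.seed)
    I_noisy = np.empty_like(I_clean)
    n_resampled = 0
    for j, i0 in enumerate(I_clean):
        val = i0 * (1.0 + spec.noise_rel * rng.standard_normal())
        while val <= 0:
            n_resampled += 1
            val = i0 * (1.0 + spec.noise_rel * rng.standard_normal())
        I_noisy[j] = val
    if n_resampled > 0.1 * len(I_clean):
        import warnings

        warnings.warn(
            f"{n_resampled} non-positive synthetic currents resampled; "
            "noise level is large relative to the signal"
        )
    truth = {"family": spec.truth.family, "sigma0": spec.truth.sigma0}
    if spec.truth.family == "linear":
        truth["k_sigma"] = spec.truth.k_sigma
    if spec.truth.family == "exponential":
        truth["c1"], truth["c2"] = spec.truth.c1, spec.truth.c2
    return IVDataset(
        U=U_all,
        I=I_noisy,
        provenance={
            "kind": "synthetic",
            "truth": truth,
            "noise_rel": spec.noise_rel,
            "seed": spec.seed,
            "geometry_case": spec.geometry.case,
            "replicates": spec.replicates,
        },
    )
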