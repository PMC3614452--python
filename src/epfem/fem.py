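"""Galerkin P1 discretization of the current-conservation equation.

Solves -div(sigma grad phi) = 0 on a tagged tetrahedral mesh for a *fixed*
per-element conductivity (scalar or 3x3 tensor), with Dirichlet potentials on
the electrode contacts and the natural zero-flux condition elsewhere.  Linear
(P1) tetrahedra make the electric field E = -grad phi constant per element,
which is where the field-dependent conductivity sigma(|E|) naturally lives.

Electrode currents are extracted from the residual of the unconstrained
system at the Dirichlet nodes (reaction flux): this is the variationally
consistent boundary flux and is superconvergent compared with direct surface
quadrature of J.n (which is kept as a cross-check, see
:func:`surface_current`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Union

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import ANODE, CATHODE, FACET_TAGS, Mesh
from .units import V_PER_CM, vm_to_vcm


class SolveError(RuntimeError):
    """Linear-solver breakdown or invalid system."""


# ---------------------------------------------------------------------------
# element geometry (cached per mesh)
# ---------------------------------------------------------------------------

@dataclass
class ElementGeometry:
    volumes: np.ndarray      # (m,)
    grads: np.ndarray        # (m, 4, 3) shape-function gradients, 1/m


def element_geometry(mesh: Mesh) -> ElementGeometry:
    cached = getattr(mesh, "_elem_geom", None)
    if cached is not None:
        return cached
    p = mesh.points[mesh.tets]                      # (m, 4, 3)
    T = p[:, 1:] - p[:, :1]                         # (m, 3, 3) edge vectors
    det = np.linalg.det(T)
    vol = det / 6.0
    if np.any(np.abs(vol) < 1e-300):
        raise SolveError(
            f"singular element geometry in element {int(np.argmin(np.abs(vol)))}"
        )
    Tinv = np.linalg.inv(T)                         # rows ~ grad of barycentric
    g123 = np.transpose(Tinv, (0, 2, 1))            # (m, 3, 3): grads of N1..N3
    g0 = -g123.sum(axis=1, keepdims=True)
    grads = np.concatenate([g0, g123], axis=1)      # (m, 4, 3)
    geom = ElementGeometry(volumes=np.abs(vol), grads=grads)
    mesh._elem_geom = geom
    return geom


def _element_matrices(mesh: Mesh, sigma_elem: np.ndarray) -> np.ndarray:
    """Per-element 4x4 stiffness integral(grad N . sigma . grad N^T) dV."""
    geom = element_geometry(mesh)
    G, V = geom.grads, geom.volumes
    sigma_elem = np.asarray(sigma_elem, dtype=float)
    if sigma_elem.ndim == 1:
        Ke = np.einsum("e,eai,ebi->eab", V * sigma_elem, G, G)
    elif sigma_elem.ndim == 3:
        Ke = np.einsum("e,eai,eij,ebj->eab", V, G, sigma_elem, G)
    else:
        raise SolveError("sigma_elem must be (m,) scalars or (m,3,3) tensors")
    return Ke


def assemble_stiffness(mesh: Mesh, sigma_elem: np.ndarray) -> sp.csr_matrix:
    """Assemble the global (unconstrained) stiffness matrix, S/m units."""
    Ke = _element_matrices(mesh, sigma_elem)
    rows = np.repeat(mesh.tets, 4, axis=1).reshape(-1)
    cols = np.tile(mesh.tets, (1, 4)).reshape(-1)
    K = sp.coo_matrix(
        (Ke.reshape(-1), (rows, cols)), shape=(mesh.n_nodes, mesh.n_nodes)
    )
    return K.tocsr()


def stiffness_action(mesh: Mesh, sigma_elem: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Compute K(sigma_elem) @ phi without assembling the sparse matrix."""
    Ke = _element_matrices(mesh, sigma_elem)
    pe = phi[mesh.tets]                              # (m, 4)
    re = np.einsum("eab,eb->ea", Ke, pe)
    out = np.zeros(mesh.n_nodes)
    np.add.at(out, mesh.tets.reshape(-1), re.reshape(-1))
    return out


# ---------------------------------------------------------------------------
# constrained linear system
# ---------------------------------------------------------------------------

@dataclass
class LinearSystem:
    """Dirichlet-reduced SPD system K_ff phi_f = -K_fc phi_c."""

    K: sp.csr_matrix          # full, unconstrained
    free: np.ndarray
    fixed: np.ndarray
    fixed_values: np.ndarray

    def solve(self) -> np.ndarray:
        Kff = self.K[self.free][:, self.free].tocsc()
        Kfc = self.K[self.free][:, self.fixed]
        rhs = -Kfc @ self.fixed_values
        try:
            phi_f = spla.spsolve(Kff, rhs)
        except Exception as exc:  # pragma: no cover - solver breakdown
            raise SolveError(f"sparse solve failed: {exc}") from exc
        if not np.all(np.isfinite(phi_f)):
            raise SolveError("sparse solve returned non-finite values")
        phi = np.zeros(self.K.shape[0])
        phi[self.free] = phi_f
        phi[self.fixed] = self.fixed_values
        return phi


def dirichlet_system(mesh: Mesh, sigma_elem: np.ndarray,
                     potentials: Dict[str, float]) -> LinearSystem:
    """Assemble with electrode-tag -> potential Dirichlet data."""
    for tag in ("anode", "cathode"):
        if tag not in potentials:
            raise SolveError(f"missing Dirichlet potential for {tag!r}")
    K = assemble_stiffness(mesh, sigma_elem)
    fixed_nodes = []
    fixed_vals = []
    for tag, val in potentials.items():
        nodes = mesh.electrode_nodes(tag)
        fixed_nodes.append(nodes)
        fixed_vals.append(np.full(len(nodes), float(val)))
    fixed = np.concatenate(fixed_nodes)
    vals = np.concatenate(fixed_vals)
    order = np.argsort(fixed)
    fixed, vals = fixed[order], vals[order]
    free = np.setdiff1d(np.arange(mesh.n_nodes), fixed)
    return LinearSystem(K=K, free=free, fixed=fixed, fixed_values=vals)


# ---------------------------------------------------------------------------
# solution container
# ---------------------------------------------------------------------------

@dataclass
class FieldSolution:
    """Solved potential field with derived element data.

    ``phi`` nodal potentials [V]; ``E`` per-element field vectors [V/m];
    ``sigma_elem`` the conductivity used in the solve ((m,) or (m,3,3), S/m);
    ``currents`` injected current per electrode tag [A] (positive into the
    tissue at the anode for U > 0).
    """

    mesh: Mesh
    phi: np.ndarray
    E: np.ndarray
    sigma_elem: np.ndarray
    U: float
    currents: Dict[str, float]

    @property
    def E_mag_vcm(self) -> np.ndarray:
        """Per-element field magnitude in V/cm."""
        return vm_to_vcm(np.linalg.norm(self.E, axis=1))

    @property
    def J(self) -> np.ndarray:
        """Per-element current density [A/m^2]."""
        if self.sigma_elem.ndim == 1:
            return self.sigma_elem[:, None] * self.E
        return np.einsum("eij,ej->ei", self.sigma_elem, self.E)

    @property
    def I(self) -> float:
        """Anode (injected) current [A]."""
        return self.currents["anode"]

    def energy(self) -> float:
        """Dissipated power integral sigma |grad phi|^2 dV [W]."""
        geom = element_geometry(self.mesh)
        return float(np.einsum("e,ei,ei->", geom.volumes, self.J, self.E))


def element_field(mesh: Mesh, phi: np.ndarray) -> np.ndarray:
    """Per-element E = -grad phi [V/m]."""
    geom = element_geometry(mesh)
    return -np.einsum("eai,ea->ei", geom.grads, phi[mesh.tets])


def reaction_currents(mesh: Mesh, sigma_elem: np.ndarray,
                      phi: np.ndarray) -> Dict[str, float]:
    """Electrode currents from the unconstrained residual at Dirichlet nodes."""
    r = stiffness_action(mesh, sigma_elem, phi)
    out = {}
    for tag in ("anode", "cathode"):
        out[tag] = float(r[mesh.electrode_nodes(tag)].sum())
    return out


def solve_fixed_sigma(mesh: Mesh, sigma_elem: np.ndarray, U: float) -> FieldSolution:
    """Solve the linear problem with fixed conductivity, anode at U, cathode 0."""
    sigma_elem = np.asarray(sigma_elem, dtype=float)
    sys = dirichlet_system(mesh, sigma_elem, {"anode": float(U), "cathode": 0.0})
    phi = sys.solve()
    E = element_field(mesh, phi)
    currents = reaction_currents(mesh, sigma_elem, phi)
    return FieldSolution(
        mesh=mesh, phi=phi, E=E, sigma_elem=sigma_elem, U=float(U),
        currents=currents,
    )


def compute_current(solution: FieldSolution, tag: str = "anode") -> float:
    """Variationally consistent boundary flux through the tagged contact [A]."""
    if tag not in ("anode", "cathode"):
        raise SolveError(f"unknown electrode tag {tag!r}")
    return solution.currents[tag]


def surface_current(solution: FieldSolution, tag: str = "anode") -> float:
    """Independent oracle: direct surface quadrature of J.n over the contact.

    Returns the current *entering* the domain through the tagged contact, so
    it matches :func:`compute_current` at the anode for U > 0.
    """
    mesh = solution.mesh
    tid = FACET_TAGS.index(tag)
    sel = np.flatnonzero(mesh.bfacet_tags == tid)
    if sel.size == 0:
        raise SolveError(f"no facets tagged {tag!r}")
    # facet -> owning element
    face_map = {}
    for e, tet in enumerate(mesh.tets):
        for idx in ((0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)):
            face_map.setdefault(tuple(sorted(tet[list(idx)])), e)
    J = solution.J
    total = 0.0
    vols_cent = mesh.points[mesh.tets].mean(axis=1)
    for fi in sel:
        tri = mesh.bfacets[fi]
        e = face_map[tuple(sorted(tri))]
        p = mesh.points[tri]
        n = np.cross(p[1] - p[0], p[2] - p[0]) / 2.0   # area-weighted normal
        # orient outward: away from the owning element centroid
        if np.dot(n, p.mean(axis=0) - vols_cent[e]) < 0:
            n = -n
        total += float(np.dot(J[e], n))
    return -total  # inward current


def full_newton_tangent(mesh: Mesh, sigma_elem: np.ndarray,
                        dsigma_dE_vcm: np.ndarray, E: np.ndarray) -> sp.csr_matrix:
    """Consistent tangent of the residual for sigma = sigma(|E|).

    ``dsigma_dE_vcm`` holds d sigma/dE in S/m per V/cm per element: a scalar
    array (m,) for isotropic tissues, or a (m,3,3) lab-frame tensor of
    per-axis slopes for anisotropic ones.  ``E`` is the element field in
    V/m.  On top of the secant stiffness K(sigma) each element contributes
    the rank-one linearization of the conductivity,

        (1/|E|) * V_e * (G (sigma' E)) (G E)^T,

    which is symmetric for isotropic sigma and mildly non-symmetric
    otherwise (handled by the direct solver either way).
    """
    K = assemble_stiffness(mesh, sigma_elem)
    geom = element_geometry(mesh)
    emag = np.linalg.norm(E, axis=1)
    slope_si = np.asarray(dsigma_dE_vcm) / V_PER_CM        # S/m per V/m
    c = np.where(emag > 0, geom.volumes / np.maximum(emag, 1e-300), 0.0)
    if slope_si.ndim == 1:
        sE = slope_si[:, None] * E
    else:
        sE = np.einsum("eij,ej->ei", slope_si, E)
    a = np.einsum("eai,ei->ea", geom.grads, sE)            # (m, 4)
    b = np.einsum("eai,ei->ea", geom.grads, E)             # (m, 4)
    Be = c[:, None, None] * a[:, :, None] * b[:, None, :]
    rows = np.repeat(mesh.tets, 4, axis=1).reshape(-1)
    cols = np.tile(mesh.tets, (1, 4)).reshape(-1)
    B = sp.coo_matrix(
        (Be.reshape(-1), (rows, cols)), shape=(mesh.n_nodes, mesh.n_nodes)
    )
    return (K + B.tocsr()).tocsr()
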