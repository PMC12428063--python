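"""Quasi-static current continuity in axisymmetric coordinates.

Solves div(sigma grad V) = 0 in the meridian plane with the axisymmetric
weight r, Dirichlet conditions on the energised electrode and the
grounding pad, and zero normal current elsewhere (insulation, symmetry
axis, far field).  The nanosecond pulses are far slower than tissue charge
relaxation at these conductivities, so each pulse is treated as a DC
conduction problem; tissue permittivity is neglected.

Internal units: lengths cm, potential V, field V/cm, conductivity S/cm
(converted from the S/m input), current A.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield
from functools import cached_property

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import _integrate
from .geometry import ELECTRODE, PAD
from .mesh import Mesh, RefinementRule, refine_mesh

__all__ = ["MaterialProperties", "FieldSolution", "solve_potential",
           "adaptive_solve", "volume_above_field", "field_volume_curve"]


class SolverError(RuntimeError):
    pass


@dataclass(frozen=True)
class MaterialProperties:
    """Bulk liver tissue properties.

    ``sigma0`` (S/m) is the baseline electrical conductivity at
    ``reference_temperature``; conductivity varies linearly with
    temperature, sigma(T) = sigma0 * (1 + alpha * (T - T_ref)).  The
    thermal constants are liver values from the IT'IS tissue-property
    database (implementer defaults; see docs/methods.md).
    """

    sigma0: float = 0.4            # S/m
    alpha: float = 0.015           # 1/degC, linear temperature coefficient
    reference_temperature: float = 33.0  # degC
    rho: float = 1079.0            # kg/m^3
    cp: float = 3540.0             # J/(kg K)
    k: float = 0.52                # W/(m K)

    def __post_init__(self) -> None:
        for name in ("sigma0", "rho", "cp", "k"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} > 0 required")

    def sigma(self, temperature) -> np.ndarray:
        """Conductivity in S/m at the given temperature(s)."""
        t = np.asarray(temperature, dtype=float)
        return self.sigma0 * (1.0 + self.alpha * (t - self.reference_temperature))

    # cm-based coefficients used by the solvers
    @property
    def sigma0_cm(self) -> float:
        return self.sigma0 / 100.0           # S/cm

    @property
    def k_cm(self) -> float:
        return self.k / 100.0                # W/(cm K)

    @property
    def volumetric_heat_capacity_cm(self) -> float:
        return self.rho * self.cp * 1e-6     # J/(cm^3 K)


def p1_gradients(mesh: Mesh):
    """P1 shape-function gradients (T, 3, 2) and element areas."""
    p = mesh.points[mesh.triangles]
    v0, v1, v2 = p[:, 0], p[:, 1], p[:, 2]
    area2 = ((v1 - v0)[:, 0] * (v2 - v0)[:, 1]
             - (v1 - v0)[:, 1] * (v2 - v0)[:, 0])
    grads = np.empty((mesh.n_triangles, 3, 2))
    # grad lambda_i = rot90(opposite edge) / (2A)
    for i, (a, b) in enumerate(((1, 2), (2, 0), (0, 1))):
        e = p[:, b] - p[:, a]
        grads[:, i, 0] = -e[:, 1]
        grads[:, i, 1] = e[:, 0]
    grads /= area2[:, None, None]
    return grads, 0.5 * area2


def assemble_stiffness(mesh: Mesh, coeff: np.ndarray) -> sp.csr_matrix:
    """Assemble sum_e coeff_e * A_e * (grad_i . grad_j) as CSR."""
    grads, areas = p1_gradients(mesh)
    ke = np.einsum("tid,tjd->tij", grads, grads) * (coeff * areas)[:, None, None]
    t = mesh.triangles
    rows = np.repeat(t, 3, axis=1).ravel()
    cols = np.tile(t, (1, 3)).ravel()
    K = sp.coo_matrix((ke.ravel(), (rows, cols)),
                      shape=(mesh.n_points, mesh.n_points))
    return K.tocsr()


def dirichlet_solve(K: sp.csr_matrix, fixed_idx: np.ndarray,
                    fixed_val: np.ndarray, rhs: np.ndarray | None = None) -> np.ndarray:
    """Solve K u = rhs with u[fixed_idx] = fixed_val prescribed."""
    n = K.shape[0]
    if rhs is None:
        rhs = np.zeros(n)
    free = np.ones(n, dtype=bool)
    free[fixed_idx] = False
    u = np.zeros(n)
    u[fixed_idx] = fixed_val
    b = rhs[free] - K[free][:, fixed_idx] @ fixed_val
    A = K[free][:, free].tocsc()
    u[free] = spla.spsolve(A, b)
    if not np.isfinite(u).all():
        raise SolverError("linear solve produced non-finite values")
    return u


@dataclass
class FieldSolution:
    """Electrostatic solution on a mesh.

    ``e_field``/``e_magnitude`` are element-wise in V/cm,
    ``current_density`` in A/cm^2; ``electrode_current``/``pad_current``
    are the total currents (A) through the respective surfaces, both
    positive for current flowing electrode -> tissue -> pad.
    """

    mesh: Mesh
    potential: np.ndarray
    e_field: np.ndarray
    e_magnitude: np.ndarray
    sigma_elem_cm: np.ndarray
    current_density: np.ndarray
    electrode_current: float
    pad_current: float
    applied_voltage: float
    provenance: dict = dfield(default_factory=dict)

    @cached_property
    def nodal_e_magnitude(self) -> np.ndarray:
        return _integrate.nodal_from_element(
            self.mesh.points, self.mesh.triangles, self.e_magnitude)


def solve_potential(mesh: Mesh, materials: MaterialProperties,
                    temperature: np.ndarray | None = None,
                    applied_voltage: float = 6000.0) -> FieldSolution:
    """Solve the conduction problem at the given applied voltage.

    If a nodal ``temperature`` field (degC) is supplied, the conductivity
    of each element follows the linear law at its mean vertex temperature;
    otherwise the baseline (uniform sigma) problem is solved, whose field
    distribution is independent of the conductivity magnitude.
    """
    if applied_voltage < 0:
        raise ValueError("applied_voltage >= 0")
    if temperature is None:
        sigma_e = np.full(mesh.n_triangles, materials.sigma0_cm)
    else:
        temperature = np.asarray(temperature, dtype=float)
        if temperature.shape != (mesh.n_points,):
            raise SolverError("temperature field is not defined on this mesh")
        t_elem = temperature[mesh.triangles].mean(axis=1)
        sigma_e = materials.sigma(t_elem) / 100.0
        if (sigma_e <= 0).any():
            raise SolverError("sigma(T) <= 0 in at least one element")

    rbar = mesh.centroids[:, 0]
    K = assemble_stiffness(mesh, sigma_e * rbar)

    el_nodes = mesh.nodes_on(ELECTRODE)
    pad_nodes = mesh.nodes_on(PAD)
    if len(el_nodes) == 0 or len(pad_nodes) == 0:
        raise SolverError("missing Dirichlet boundary (ELECTRODE or PAD)")
    fixed = np.concatenate([el_nodes, pad_nodes])
    vals = np.concatenate([np.full(len(el_nodes), float(applied_voltage)),
                           np.zeros(len(pad_nodes))])
    V = dirichlet_solve(K, fixed, vals)

    grads, _ = p1_gradients(mesh)
    E = -np.einsum("tid,ti->td", grads, V[mesh.triangles])  # V/cm
    emag = np.linalg.norm(E, axis=1)
    J = sigma_e[:, None] * E                                # A/cm^2

    resid = K @ V
    i_el = 2.0 * np.pi * resid[el_nodes].sum()
    i_pad = -2.0 * np.pi * resid[pad_nodes].sum()
    return FieldSolution(mesh=mesh, potential=V, e_field=E, e_magnitude=emag,
                         sigma_elem_cm=sigma_e, current_density=J,
                         electrode_current=float(i_el), pad_current=float(i_pad),
                         applied_voltage=float(applied_voltage))


def adaptive_solve(mesh: Mesh, materials: MaterialProperties,
                   applied_voltage: float = 6000.0,
                   rule: RefinementRule | None = None,
                   temperature: np.ndarray | None = None):
    """Solve, then apply ``rule.rounds`` field-driven refinement passes.

    Returns ``(field, history)`` where ``field`` is the solution on the
    final mesh and ``history`` records (n_triangles, electrode_current)
    after each solve (for mesh-convergence reporting).
    """
    rule = rule or RefinementRule()
    field = solve_potential(mesh, materials, temperature, applied_voltage)
    history = [(mesh.n_triangles, field.electrode_current)]
    one_round = RefinementRule(field_threshold=rule.field_threshold, rounds=1,
                               shrink_factor=rule.shrink_factor)
    for _ in range(rule.rounds):
        new_mesh = refine_mesh(field.mesh, field, one_round)
        if new_mesh is field.mesh:
            break
        field = solve_potential(new_mesh, materials, temperature, applied_voltage)
        history.append((new_mesh.n_triangles, field.electrode_current))
    return field, history


def volume_above_field(field: FieldSolution, e_set: float,
                       method: str = "interpolated") -> float:
    """Tissue volume (cm^3) where |E| exceeds ``e_set`` (V/cm).

    ``interpolated`` clips elements at the iso-contour of the nodal field;
    ``element`` counts whole elements above the threshold (the coarser
    estimate on the raw element field).
    """
    if e_set < 0:
        raise ValueError("e_set >= 0")
    m = field.mesh
    if e_set == 0:
        return _integrate.revolved_volume(m.points, m.triangles)
    if method == "element":
        return _integrate.revolved_volume(m.points, m.triangles,
                                          field.e_magnitude > e_set)
    if method != "interpolated":
        raise ValueError("method must be 'interpolated' or 'element'")
    return float(_integrate.superlevel_volumes(
        m.points, m.triangles, field.nodal_e_magnitude, [e_set])[0])


def field_volume_curve(field: FieldSolution, e_grid: np.ndarray,
                       method: str = "interpolated") -> np.ndarray:
    """Volumes (cm^3) above each field level of ``e_grid`` (V/cm)."""
    e_grid = np.asarray(e_grid, dtype=float)
    if method == "interpolated":
        return _integrate.superlevel_volumes(
            field.mesh.points, field.mesh.triangles,
            field.nodal_e_magnitude, e_grid)
    return np.array([volume_above_field(field, e, method) for e in e_grid])
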