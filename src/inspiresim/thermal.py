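"""Transient axisymmetric heat conduction driven by the duty-cycled Joule
source.

The temperature field obeys rho*Cp dT/dt = div(k grad T) + Qe with
Qe = R(t)*1e-6 * (J . E): the energy delivery rate R(t) (microseconds of
pulse-on time per second) scales the continuous-delivery Joule power
density down to its duty-cycled time average.  The coolant loop inside the
needle is represented by a boundary condition on the shaft wall over the
cooled length (everything proximal of the uncooled distal tip): either a
convective (Robin) film condition or a fixed wall temperature.  The far
field and the grounding-pad face are held at the baseline tissue
temperature.  No perfusion sink is included by default, matching the
stated heat equation; a Pennes term is available via
``perfusion_w_per_m3k``.

Time stepping is implicit (backward) Euler with a lumped mass matrix:
unconditionally stable, monotone, and one sparse back-substitution per
step once the operator is factorised.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import _integrate
from ._integrate import _cross2
from .geometry import CHANNEL, FARFIELD, PAD
from .electro import FieldSolution, MaterialProperties, assemble_stiffness
from .mesh import Mesh

__all__ = ["ThermalBoundary", "ThermalState", "ThermalSolver", "joule_source",
           "probe_temperature"]


class ThermalError(RuntimeError):
    pass


@dataclass(frozen=True)
class ThermalBoundary:
    """Boundary/initial conditions for the tissue heat problem.

    ``baseline_tissue_temperature`` (degC) initialises the tissue and fixes
    the far boundary; ``coolant_temperature`` with ``coolant_model`` acts on
    the cooled shaft wall.  The default film coefficient is an effective
    outer-wall value for the 10 mL/min water loop (implementer default, see
    docs/methods.md).
    """

    baseline_tissue_temperature: float = 33.0
    coolant_temperature: float = 22.0
    coolant_model: str = "convective"          # "convective" | "fixed"
    film_coefficient: float = 1300.0           # W/(m^2 K)

    def __post_init__(self) -> None:
        if self.coolant_model not in ("convective", "fixed"):
            raise ValueError("coolant_model must be 'convective' or 'fixed'")
        if self.coolant_model == "convective" and not self.film_coefficient > 0:
            raise ValueError("film_coefficient > 0 required for convective model")


@dataclass
class ThermalState:
    """Nodal temperature (degC) at a simulation time (s)."""

    mesh: Mesh
    temperature: np.ndarray
    time: float = 0.0

    def iso_volume_above(self, level: float) -> float:
        """Tissue volume (cm^3) hotter than ``level`` (degC)."""
        return float(_integrate.superlevel_volumes(
            self.mesh.points, self.mesh.triangles, self.temperature, [level])[0])

    def hottest_point(self) -> tuple[float, float]:
        """(r, z) of the hottest node."""
        i = int(np.argmax(self.temperature))
        return tuple(self.mesh.points[i])


def joule_source(field: FieldSolution, rate: float) -> np.ndarray:
    """Duty-cycle-scaled Joule power density per element (W/cm^3).

    ``rate`` is the energy delivery rate in us of pulse-on time per second;
    at rate = 1e6 (continuous delivery) the source equals sigma*|E|^2.
    """
    if rate < 0:
        raise ValueError("rate >= 0")
    je = np.einsum("td,td->t", field.current_density, field.e_field)  # W/cm^3
    return (rate * 1e-6) * je


class ThermalSolver:
    """Implicit-Euler conduction solver bound to one mesh.

    The operator (mass/dt + stiffness + film terms, with Dirichlet rows
    eliminated) is factorised once per time-step size and reused, so a
    treatment simulation costs one back-substitution per step.
    """

    def __init__(self, mesh: Mesh, materials: MaterialProperties,
                 boundary: ThermalBoundary,
                 perfusion_w_per_m3k: float = 0.0):
        self.mesh = mesh
        self.materials = materials
        self.boundary = boundary
        rbar = mesh.centroids[:, 0]
        areas = mesh.areas

        self.K = assemble_stiffness(mesh, materials.k_cm * rbar)
        if perfusion_w_per_m3k > 0:
            w_cm = perfusion_w_per_m3k * 1e-6           # W/(cm^3 K)
            lump = w_cm * areas * rbar / 3.0
            data = np.repeat(lump, 3)
            idx = mesh.triangles.ravel()
            R = sp.coo_matrix((data, (idx, idx)),
                              shape=(mesh.n_points, mesh.n_points)).tocsr()
            self.K = self.K + R
            self._perf_rhs = np.asarray(
                R.sum(axis=1)).ravel() * boundary.baseline_tissue_temperature
        else:
            self._perf_rhs = np.zeros(mesh.n_points)

        # lumped mass: rho*Cp * integral(w_i r dA)
        rc = materials.volumetric_heat_capacity_cm  # J/(cm^3 K)
        lump = rc * areas * rbar / 3.0
        self.mass = np.zeros(mesh.n_points)
        for k in range(3):
            np.add.at(self.mass, mesh.triangles[:, k], lump)

        # fixed far boundary (outer walls + pad face) at baseline temperature
        fixed = set(mesh.nodes_on(FARFIELD)) | set(mesh.nodes_on(PAD))
        self._robin_rhs = np.zeros(mesh.n_points)
        cooled = mesh.edges_on(CHANNEL)
        if boundary.coolant_model == "fixed":
            fixed |= set(np.unique(cooled))
        elif len(cooled):
            h_cm = boundary.film_coefficient / 1e4      # W/(cm^2 K)
            p0 = mesh.points[cooled[:, 0]]
            p1 = mesh.points[cooled[:, 1]]
            ell = np.hypot(*(p1 - p0).T)
            r0, r1 = p0[:, 0], p1[:, 0]
            # row-lumped integral(w_i r ds) per edge: keeps the discrete
            # operator monotone (no undershoot below coolant temperature)
            m00 = ell * (2 * r0 + r1) / 6.0
            m11 = ell * (r0 + 2 * r1) / 6.0
            rows = np.concatenate([cooled[:, 0], cooled[:, 1]])
            cols = np.concatenate([cooled[:, 0], cooled[:, 1]])
            vals = h_cm * np.concatenate([m00, m11])
            Rb = sp.coo_matrix((vals, (rows, cols)),
                               shape=(mesh.n_points, mesh.n_points)).tocsr()
            self.K = self.K + Rb
            self._robin_rhs = np.asarray(Rb.sum(axis=1)).ravel() \
                * boundary.coolant_temperature

        self.fixed = np.fromiter(sorted(fixed), dtype=np.int64) if fixed \
            else np.empty(0, dtype=np.int64)
        self._fixed_vals = np.empty(len(self.fixed))
        self._fixed_vals[:] = boundary.baseline_tissue_temperature
        if boundary.coolant_model == "fixed" and len(cooled):
            in_cooled = np.isin(self.fixed, np.unique(cooled))
            self._fixed_vals[in_cooled] = boundary.coolant_temperature

        self.free = np.ones(mesh.n_points, dtype=bool)
        self.free[self.fixed] = False
        self._lu = None
        self._lu_dt = None

    def initial_state(self) -> ThermalState:
        T0 = np.full(self.mesh.n_points,
                     self.boundary.baseline_tissue_temperature)
        T0[self.fixed] = self._fixed_vals
        return ThermalState(self.mesh, T0, 0.0)

    def steady_state(self, qe_elem: np.ndarray | None = None) -> ThermalState:
        """Steady conduction solution (e.g. the pre-treatment cooled state).

        With no source this is the tissue after the coolant loop has run to
        equilibrium, which is how treatments begin: the probe then reads a
        few degrees above the coolant, as observed at treatment start.
        """
        F = self._robin_rhs + self._perf_rhs
        if qe_elem is not None:
            F = F + self.source_load(qe_elem)
        A = self.K.tocsr()
        T = np.empty(self.mesh.n_points)
        T[self.fixed] = self._fixed_vals
        rhs = F[self.free]
        if len(self.fixed):
            rhs = rhs - A[self.free][:, self.fixed] @ self._fixed_vals
        T[self.free] = spla.spsolve(A[self.free][:, self.free].tocsc(), rhs)
        if not np.isfinite(T).all():
            raise ThermalError("steady-state solve produced non-finite values")
        return ThermalState(self.mesh, T, 0.0)

    def source_load(self, qe_elem: np.ndarray) -> np.ndarray:
        """Nodal load vector (W) from an element power density (W/cm^3)."""
        rbar = self.mesh.centroids[:, 0]
        lump = np.asarray(qe_elem) * self.mesh.areas * rbar / 3.0
        F = np.zeros(self.mesh.n_points)
        for k in range(3):
            np.add.at(F, self.mesh.triangles[:, k], lump)
        return F

    def _factorise(self, dt: float):
        if self._lu is None or self._lu_dt != dt:
            A = sp.diags(self.mass / dt) + self.K
            self._A = A.tocsr()
            Aff = self._A[self.free][:, self.free].tocsc()
            self._Afc = self._A[self.free][:, self.fixed]
            self._lu = spla.splu(Aff)
            self._lu_dt = dt

    def step(self, state: ThermalState, qe_elem: np.ndarray | None,
             dt: float) -> ThermalState:
        """Advance one implicit Euler step with the given element source."""
        if not dt > 0:
            raise ValueError("dt > 0")
        T = state.temperature
        if T.shape != (self.mesh.n_points,):
            raise ThermalError("state is not defined on this mesh")
        self._factorise(dt)
        F = self._robin_rhs + self._perf_rhs
        if qe_elem is not None:
            F = F + self.source_load(qe_elem)
        b = self.mass / dt * T + F
        Tn = np.empty_like(T)
        Tn[self.fixed] = self._fixed_vals
        rhs = b[self.free]
        if len(self.fixed):
            rhs = rhs - self._Afc @ self._fixed_vals
        Tn[self.free] = self._lu.solve(rhs)
        if not np.isfinite(Tn).all():
            raise ThermalError(f"non-finite temperature at t={state.time + dt}")
        return ThermalState(self.mesh, Tn, state.time + dt)


def probe_temperature(state: ThermalState, location) -> float:
    """Linearly interpolated temperature at an (r, z) point (degC)."""
    mesh = state.mesh
    p = np.asarray(location, dtype=float)
    tri = _find_triangle(mesh, p)
    a, b, c = mesh.points[mesh.triangles[tri]]
    den = _cross2(b - a, c - a)
    l1 = _cross2(p - a, c - a) / den
    l2 = _cross2(b - a, p - a) / den
    lam = np.array([1.0 - l1 - l2, l1, l2])
    return float(lam @ state.temperature[mesh.triangles[tri]])


def _find_triangle(mesh: Mesh, p: np.ndarray, tol: float = 1e-9) -> int:
    cache = getattr(mesh, "_tri_cache", None)
    if cache is None:
        cache = mesh._tri_cache = {}
    key = (float(p[0]), float(p[1]))
    if key in cache:
        return cache[key]
    pts = mesh.points[mesh.triangles]
    a, b, c = pts[:, 0], pts[:, 1], pts[:, 2]
    den = _cross2(b - a, c - a)
    l1 = _cross2(p - a, c - a) / den
    l2 = _cross2(b - a, p - a) / den
    l0 = 1.0 - l1 - l2
    inside = (l0 >= -tol) & (l1 >= -tol) & (l2 >= -tol)
    idx = np.nonzero(inside)[0]
    if len(idx) == 0:
        raise ThermalError(f"probe location {tuple(p)} is outside the mesh")
    cache[key] = int(idx[0])
    return cache[key]
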