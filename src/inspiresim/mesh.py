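"""Triangular meshing of the axisymmetric domain with adaptive refinement.

A graded structured background mesh resolves the needle geometry; local
refinement is performed by conforming red-green-blue (longest-edge)
subdivision, both to reach the prescribed element size near the electrode
and, driven by the solved field, to refine wherever the field magnitude
exceeds the refinement threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from typing import Callable

import numpy as np

from .geometry import (AXIS, CHANNEL, ELECTRODE, FARFIELD, INSULATION, PAD,
                       GeometryError, ProblemGeometry)

__all__ = ["Mesh", "RefinementRule", "generate_mesh", "refine_mesh",
           "refine_marked", "rectangle_mesh", "spherical_shell_mesh"]

_SQRT2 = float(np.sqrt(2.0))


def _cross2(a, b):
    """z-component of the cross product of 2-D vectors."""
    return a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]


class MeshError(RuntimeError):
    pass


@dataclass(frozen=True)
class RefinementRule:
    """Field-driven refinement: subdivide every element above the threshold.

    ``field_threshold`` is in V/cm; ``rounds`` is the number of solve/refine
    cycles applied by the caller-facing adaptive driver.  Longest-edge
    subdivision halves marked edges, so ``shrink_factor`` is fixed at 0.5
    and retained only for documentation of the rule.
    """

    field_threshold: float = 250.0
    rounds: int = 2
    shrink_factor: float = 0.5

    def __post_init__(self) -> None:
        if not self.field_threshold > 0:
            raise ValueError("field_threshold > 0")
        if self.rounds < 0:
            raise ValueError("rounds >= 0")


class Mesh:
    """Conforming triangle mesh of the meridian (r, z) plane.

    ``tagger`` maps boundary-edge midpoints to boundary tags; meshes built
    from a :class:`~inspiresim.geometry.ProblemGeometry` use its geometric
    classifier so tags survive refinement without bookkeeping.
    """

    def __init__(self, points: np.ndarray, triangles: np.ndarray,
                 geometry: ProblemGeometry | None = None,
                 tagger: Callable[[np.ndarray], np.ndarray] | None = None):
        points = np.asarray(points, dtype=float)
        triangles = np.asarray(triangles, dtype=np.int64)
        if points.ndim != 2 or points.shape[1] != 2:
            raise MeshError("points must be (n, 2)")
        if (points[:, 0] < -1e-12).any():
            raise MeshError("all r >= 0 required in axisymmetric mesh")
        # enforce counter-clockwise orientation
        p = points[triangles]
        sgn = _cross2(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        flip = sgn < 0
        if flip.any():
            triangles = triangles.copy()
            triangles[flip, 1], triangles[flip, 2] = (
                triangles[flip, 2], triangles[flip, 1])
        self.points = points
        self.triangles = triangles
        self.geometry = geometry
        if tagger is None and geometry is not None:
            tagger = geometry.classify_boundary_edges
        self._tagger = tagger

    # -- basic quantities ------------------------------------------------

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    @cached_property
    def areas(self) -> np.ndarray:
        p = self.points[self.triangles]
        return 0.5 * _cross2(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])

    @cached_property
    def centroids(self) -> np.ndarray:
        return self.points[self.triangles].mean(axis=1)

    @cached_property
    def diameters(self) -> np.ndarray:
        """Longest edge length per triangle."""
        p = self.points[self.triangles]
        e = np.stack([p[:, 2] - p[:, 1], p[:, 0] - p[:, 2], p[:, 1] - p[:, 0]])
        return np.linalg.norm(e, axis=2).max(axis=0)

    # -- edge topology ---------------------------------------------------

    @cached_property
    def _edge_data(self):
        t = self.triangles
        # local edge i is opposite local vertex i
        raw = np.concatenate([t[:, [1, 2]], t[:, [2, 0]], t[:, [0, 1]]])
        key = np.sort(raw, axis=1)
        edges, inv, counts = np.unique(key, axis=0, return_inverse=True,
                                       return_counts=True)
        elem2edge = inv.reshape(3, -1).T
        return edges, elem2edge, counts

    @property
    def edges(self) -> np.ndarray:
        return self._edge_data[0]

    @property
    def elem2edge(self) -> np.ndarray:
        return self._edge_data[1]

    @cached_property
    def boundary_edge_ids(self) -> np.ndarray:
        edges, _, counts = self._edge_data
        ids = np.nonzero(counts == 1)[0]
        if (counts > 2).any():
            raise MeshError("non-manifold edge detected")
        return ids

    @cached_property
    def boundary_tags(self) -> np.ndarray:
        if self._tagger is None:
            raise MeshError("mesh has no boundary tagger")
        be = self.edges[self.boundary_edge_ids]
        mid = 0.5 * (self.points[be[:, 0]] + self.points[be[:, 1]])
        scale = max(self.points.max(), 1.0)
        return self._tagger(mid, tol=1e-8 * scale) if self.geometry is not None \
            else self._tagger(mid)

    def edges_on(self, tag: str) -> np.ndarray:
        """Boundary edges carrying ``tag`` as (k, 2) node-index pairs.

        The pseudo-tag ``CHANNEL`` selects the cooled needle-wall subset
        (shaft wall at and above the end of the uncooled tip).
        """
        be = self.edges[self.boundary_edge_ids]
        if tag == CHANNEL:
            if self.geometry is None:
                return np.empty((0, 2), dtype=np.int64)
            g = self.geometry
            wall = np.isin(self.boundary_tags, (ELECTRODE, INSULATION))
            mid = 0.5 * (self.points[be[:, 0]] + self.points[be[:, 1]])
            tol = 1e-8 * max(self.points.max(), 1.0)
            cooled = wall & (mid[:, 1] >= g.z_cooled - tol) \
                & (mid[:, 0] >= g.applicator.shaft_radius - tol)
            return be[cooled]
        return be[self.boundary_tags == tag]

    def nodes_on(self, tag: str) -> np.ndarray:
        e = self.edges_on(tag)
        return np.unique(e)

    # -- checks ----------------------------------------------------------

    def check_conforming(self) -> None:
        _, _, counts = self._edge_data
        if not ((counts == 1) | (counts == 2)).all():
            raise MeshError("hanging nodes or non-manifold edges present")
        if (self.areas <= 0).any():
            raise MeshError("degenerate (zero-area) triangle present")


# ---------------------------------------------------------------------------
# graded line helpers and the structured background mesh
# ---------------------------------------------------------------------------

def _graded(start: float, stop: float, h0: float, hmax: float,
            ratio: float = 1.3) -> np.ndarray:
    """1-D grid from start to stop, spacing h0 at start growing to hmax."""
    if stop == start:
        return np.array([start])
    sign = 1.0 if stop > start else -1.0
    length = abs(stop - start)
    xs = [0.0]
    h = min(h0, hmax)
    while xs[-1] + h < length:
        xs.append(xs[-1] + h)
        h = min(h * ratio, hmax)
    if len(xs) > 1:
        rem = length - xs[-1]
        prev = xs[-1] - xs[-2]
        if rem < 0.4 * prev:
            # redistribute the last two gaps evenly (both stay <= hmax)
            xs[-1] = xs[-2] + 0.5 * (prev + rem)
    xs.append(length)
    return start + sign * np.asarray(xs)


def _uniform(start: float, stop: float, h: float) -> np.ndarray:
    n = max(1, int(np.ceil(abs(stop - start) / h)))
    return np.linspace(start, stop, n + 1)


def _insert_line(lines: np.ndarray, value: float,
                 snap_frac: float = 0.05) -> np.ndarray:
    """Force a grid line at ``value``.

    A neighbour within ``snap_frac`` of the local gap is moved onto the
    value (changing cell sizes by at most that fraction); otherwise the
    line is inserted, accepting a thinner cell.
    """
    lines = np.asarray(lines, dtype=float).copy()
    if np.any(np.abs(lines - value) < 1e-12):
        return lines
    i = np.searchsorted(lines, value)
    if i == 0 or i == len(lines):
        return lines
    gap = lines[i] - lines[i - 1]
    if value - lines[i - 1] < snap_frac * gap and i - 1 > 0:
        lines[i - 1] = value
        return lines
    if lines[i] - value < snap_frac * gap and i < len(lines) - 1:
        lines[i] = value
        return lines
    return np.sort(np.append(lines, value))


def _tensor_triangulation(r_lines: np.ndarray, z_lines: np.ndarray,
                          keep_cell: np.ndarray):
    """Split kept rectangular cells into triangles (alternating diagonals)."""
    nr, nz = len(r_lines), len(z_lines)
    rr, zz = np.meshgrid(r_lines, z_lines, indexing="ij")
    points = np.column_stack([rr.ravel(), zz.ravel()])

    def nid(i, j):
        return i * nz + j

    ii, jj = np.nonzero(keep_cell)
    n00 = nid(ii, jj)
    n10 = nid(ii + 1, jj)
    n01 = nid(ii, jj + 1)
    n11 = nid(ii + 1, jj + 1)
    parity = (ii + jj) % 2 == 0
    t1 = np.where(parity[:, None], np.column_stack([n00, n10, n11]),
                  np.column_stack([n00, n10, n01]))
    t2 = np.where(parity[:, None], np.column_stack([n00, n11, n01]),
                  np.column_stack([n10, n11, n01]))
    tris = np.concatenate([t1, t2])
    used = np.unique(tris)
    remap = -np.ones(len(points), dtype=np.int64)
    remap[used] = np.arange(len(used))
    return points[used], remap[tris]


def generate_mesh(geometry: ProblemGeometry,
                  max_size_near: float = 0.01,
                  max_size_far: float = 0.514,
                  band: float = 0.1,
                  grading: float = 1.3,
                  max_rounds: int = 25) -> Mesh:
    """Mesh the tissue region with the needle cut out.

    Elements whose closest vertex lies within ``band`` (cm) of the
    energised electrode surface are subdivided until their diameter is at
    most sqrt(2) * ``max_size_near`` (the diagonal of a square cell of the
    prescribed maximum size); elsewhere the target size is
    ``max_size_far``.
    """
    if not (max_size_near > 0 and max_size_far > 0):
        raise ValueError("mesh sizes must be positive")
    if max_size_near > max_size_far:
        raise ValueError("max_size_near <= max_size_far required")
    a, d = geometry.applicator, geometry.domain
    h_bg = min(max_size_far, max(4.0 * max_size_near, 0.02))

    r_lines = np.concatenate([
        _uniform(0.0, a.shaft_radius, h_bg)[:-1],
        _uniform(a.shaft_radius, a.insulated_radius, h_bg)[:-1],
        _graded(a.insulated_radius, d.domain_radius, h_bg, max_size_far, grading),
    ])
    r_lines = _insert_line(np.unique(r_lines), d.pad_radius)

    z_below = _graded(geometry.z_tip, 0.0, h_bg, max_size_far, grading)
    z_exposed = _uniform(geometry.z_tip, geometry.z_junction, h_bg)
    z_above = _graded(geometry.z_junction, geometry.z_top, h_bg, max_size_far,
                      grading)
    z_lines = np.unique(np.concatenate([z_below, z_exposed, z_above]))
    z_lines = _insert_line(z_lines, geometry.z_cooled)

    # drop cells inside the needle footprint
    r_hi = r_lines[1:]
    z_mid = 0.5 * (z_lines[:-1] + z_lines[1:])
    tol = 1e-9 * d.domain_radius
    needle_r = geometry.needle_radius_at(z_mid)
    inside = (z_mid[None, :] > geometry.z_tip - tol) & \
             (r_hi[:, None] <= needle_r[None, :] + tol)
    points, tris = _tensor_triangulation(r_lines, z_lines, ~inside)
    mesh = Mesh(points, tris, geometry=geometry)

    target = _SQRT2 * max_size_near * (1 + 1e-9)
    for _ in range(max_rounds):
        node_d = geometry.distance_to_electrode(mesh.points)
        elem_d = node_d[mesh.triangles].min(axis=1)
        mark = (elem_d <= band) & (mesh.diameters > target)
        if not mark.any():
            break
        mesh = refine_marked(mesh, mark)
    else:
        raise MeshError("electrode-band refinement did not converge")
    mesh.check_conforming()
    return mesh


# ---------------------------------------------------------------------------
# conforming red-green-blue (longest-edge) refinement
# ---------------------------------------------------------------------------

def refine_marked(mesh: Mesh, marked: np.ndarray) -> Mesh:
    """Subdivide the marked triangles, closing to a conforming mesh.

    Marked triangles are split into four (red); neighbours receive green
    (two-child) or blue (three-child) splits so no hanging nodes remain.
    Closure always includes a triangle's longest edge, which bounds shape
    degradation (standard longest-edge RGB refinement).
    """
    marked = np.asarray(marked, dtype=bool)
    if marked.shape != (mesh.n_triangles,):
        raise MeshError("marker array does not match mesh")
    if not marked.any():
        return mesh

    pts = mesh.points
    tris = mesh.triangles.copy()
    # rotate each triangle so the longest edge is local edge 0 (opposite v0)
    p = pts[tris]
    el = np.stack([p[:, 2] - p[:, 1], p[:, 0] - p[:, 2], p[:, 1] - p[:, 0]])
    lengths = np.linalg.norm(el, axis=2)
    k = np.argmax(lengths, axis=0)
    roll = np.stack([(np.arange(3) + ki) % 3 for ki in range(3)])
    tris = np.take_along_axis(tris, roll[k], axis=1)

    raw = np.concatenate([tris[:, [1, 2]], tris[:, [2, 0]], tris[:, [0, 1]]])
    key = np.sort(raw, axis=1)
    edges, inv = np.unique(key, axis=0, return_inverse=True)
    e2e = inv.reshape(3, -1).T

    medge = np.zeros(len(edges), dtype=bool)
    medge[e2e[marked].ravel()] = True
    while True:
        has = medge[e2e].any(axis=1)
        need = has & ~medge[e2e[:, 0]]
        if not need.any():
            break
        medge[e2e[need, 0]] = True

    mid_id = -np.ones(len(edges), dtype=np.int64)
    split = np.nonzero(medge)[0]
    mid_id[split] = mesh.n_points + np.arange(len(split))
    midpoints = 0.5 * (pts[edges[split, 0]] + pts[edges[split, 1]])
    new_pts = np.vstack([pts, midpoints])

    pat = medge[e2e]  # (T, 3); pat[:, 0] True wherever any is True
    v0, v1, v2 = tris[:, 0], tris[:, 1], tris[:, 2]
    m0, m1, m2 = (mid_id[e2e[:, i]] for i in range(3))

    keep = ~pat.any(axis=1)
    green = pat[:, 0] & ~pat[:, 1] & ~pat[:, 2]
    blue1 = pat[:, 0] & pat[:, 1] & ~pat[:, 2]   # also split edge (v2, v0)
    blue2 = pat[:, 0] & ~pat[:, 1] & pat[:, 2]   # also split edge (v0, v1)
    red = pat.all(axis=1)

    parts = [tris[keep]]
    g = np.nonzero(green)[0]
    parts += [np.column_stack([v0[g], v1[g], m0[g]]),
              np.column_stack([v0[g], m0[g], v2[g]])]
    b = np.nonzero(blue1)[0]
    parts += [np.column_stack([v0[b], v1[b], m0[b]]),
              np.column_stack([v0[b], m0[b], m1[b]]),
              np.column_stack([m1[b], m0[b], v2[b]])]
    b = np.nonzero(blue2)[0]
    parts += [np.column_stack([v0[b], m2[b], m0[b]]),
              np.column_stack([m2[b], v1[b], m0[b]]),
              np.column_stack([v0[b], m0[b], v2[b]])]
    r = np.nonzero(red)[0]
    parts += [np.column_stack([v0[r], m2[r], m1[r]]),
              np.column_stack([m2[r], v1[r], m0[r]]),
              np.column_stack([m1[r], m0[r], v2[r]]),
              np.column_stack([m0[r], m1[r], m2[r]])]
    new_tris = np.concatenate(parts)
    return Mesh(new_pts, new_tris, geometry=mesh.geometry, tagger=mesh._tagger)


def refine_mesh(mesh: Mesh, field, rule: RefinementRule) -> Mesh:
    """One field-driven refinement pass: split elements with |E| > threshold.

    Returns the mesh unchanged when ``rule.rounds == 0``.  The adaptive
    driver (:func:`inspiresim.electro.adaptive_solve`) re-solves the field
    and calls this ``rule.rounds`` times.
    """
    if rule.rounds == 0:
        return mesh
    emag = np.asarray(field.e_magnitude)
    if emag.shape != (mesh.n_triangles,):
        raise MeshError("field is not defined on this mesh")
    mark = emag > rule.field_threshold
    if not mark.any():
        return mesh
    out = refine_marked(mesh, mark)
    out.check_conforming()
    return out


# ---------------------------------------------------------------------------
# benchmark meshes (closed-form validation geometries)
# ---------------------------------------------------------------------------

def rectangle_mesh(r0: float, r1: float, z0: float, z1: float,
                   h: float, tags: dict[str, str] | None = None) -> Mesh:
    """Uniform mesh of an (r, z) rectangle for slab/benchmark problems.

    ``tags`` maps the sides ``left/right/bottom/top`` to boundary tags
    (default: left AXIS if on the axis else FARFIELD, right FARFIELD,
    bottom PAD, top ELECTRODE).
    """
    tags = tags or {"left": AXIS if r0 == 0 else FARFIELD, "right": FARFIELD,
                    "bottom": PAD, "top": ELECTRODE}
    r_lines = _uniform(r0, r1, h)
    z_lines = _uniform(z0, z1, h)
    keep = np.ones((len(r_lines) - 1, len(z_lines) - 1), dtype=bool)
    points, tris = _tensor_triangulation(r_lines, z_lines, keep)

    def tagger(mid, tol=1e-9):
        out = np.empty(len(mid), dtype="U10")
        out[:] = FARFIELD
        out[np.abs(mid[:, 1] - z0) < tol] = tags["bottom"]
        out[np.abs(mid[:, 1] - z1) < tol] = tags["top"]
        out[np.abs(mid[:, 0] - r0) < tol] = tags["left"]
        out[np.abs(mid[:, 0] - r1) < tol] = tags["right"]
        return out

    return Mesh(points, tris, tagger=tagger)


def spherical_shell_mesh(a: float, b: float, n_rho: int = 60,
                         n_theta: int = 60) -> Mesh:
    """Axisymmetric mesh of the shell between concentric spheres.

    Inner sphere (radius ``a``) is tagged ELECTRODE, outer (``b``) PAD;
    the polar axis is AXIS.  Radial grading is geometric so the 1/rho^2
    field is resolved near the inner sphere.
    """
    if not 0 < a < b:
        raise GeometryError("0 < a < b")
    rho = np.geomspace(a, b, n_rho + 1)
    theta = np.linspace(0.0, np.pi, n_theta + 1)
    rr = rho[:, None] * np.sin(theta)[None, :]
    zz = rho[:, None] * np.cos(theta)[None, :]
    points = np.column_stack([rr.ravel(), zz.ravel()])

    nth = n_theta + 1
    ii, jj = np.meshgrid(np.arange(n_rho), np.arange(n_theta), indexing="ij")
    ii, jj = ii.ravel(), jj.ravel()
    n00 = ii * nth + jj
    n10 = (ii + 1) * nth + jj
    n01 = ii * nth + jj + 1
    n11 = (ii + 1) * nth + jj + 1
    tris = np.concatenate([np.column_stack([n00, n10, n11]),
                           np.column_stack([n00, n11, n01])])
    # collapse duplicate pole nodes (r = 0 columns) is unnecessary: they are
    # distinct nodes along the axis, all with r ~ 0, and carry no area weight
    points[:, 0] = np.maximum(points[:, 0], 0.0)

    # boundary-edge midpoints sag below the sphere radius by ~R*dtheta^2/8
    sag = (np.pi / n_theta) ** 2 / 8.0

    def tagger(mid, tol=None):
        rad = np.hypot(mid[:, 0], mid[:, 1])
        out = np.empty(len(mid), dtype="U10")
        out[:] = AXIS
        out[np.abs(rad - a) < 3 * sag * a + 1e-9 * b] = ELECTRODE
        out[np.abs(rad - b) < 3 * sag * b + 1e-9 * b] = PAD
        out[mid[:, 0] < 1e-12 * b] = AXIS
        return out

    m = Mesh(points, tris, tagger=tagger)
    # drop exactly-degenerate triangles at the poles
    good = m.areas > 1e-14 * b * b
    return Mesh(m.points, m.triangles[good], tagger=tagger)
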