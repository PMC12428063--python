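"""Volume-of-revolution integrals over P1 fields on triangle meshes.

All routines work in meridian (r, z) coordinates: the revolved volume of a
plane region S is 2*pi * integral_S r dA.  For a triangle with a linear
integrand, integral r dA = area * centroid_r exactly, which these routines
exploit; super-level sets of a nodal (P1) field are clipped triangle by
triangle so iso-contours are located by linear interpolation.
"""

from __future__ import annotations

import numpy as np

__all__ = ["revolved_volume", "nodal_from_element", "superlevel_volumes",
           "superlevel_extent"]


def _cross2(a, b):
    """z-component of the cross product of 2-D vectors."""
    return a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]


def revolved_volume(points: np.ndarray, tris: np.ndarray,
                    mask: np.ndarray | None = None) -> float:
    """Revolved volume of (a subset of) the mesh: 2*pi*sum(rbar*A)."""
    p = points[tris]
    areas = 0.5 * _cross2(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    rbar = p[:, :, 0].mean(axis=1)
    w = areas * rbar
    if mask is not None:
        w = w[mask]
    return float(2.0 * np.pi * w.sum())


def nodal_from_element(points: np.ndarray, tris: np.ndarray,
                       elem_values: np.ndarray) -> np.ndarray:
    """Area-weighted projection of an element-wise field onto the nodes."""
    p = points[tris]
    areas = 0.5 * _cross2(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    num = np.zeros(len(points))
    den = np.zeros(len(points))
    for k in range(3):
        np.add.at(num, tris[:, k], areas * elem_values)
        np.add.at(den, tris[:, k], areas)
    return num / np.where(den > 0, den, 1.0)


def _tri_r_integral(q0, q1, q2):
    """|area| * mean(r) for triangles given as (n, 2) vertex arrays."""
    a = 0.5 * np.abs(_cross2(q1 - q0, q2 - q0))
    return a * (q0[:, 0] + q1[:, 0] + q2[:, 0]) / 3.0


def superlevel_volumes(points: np.ndarray, tris: np.ndarray,
                       nodal: np.ndarray, levels: np.ndarray) -> np.ndarray:
    """Revolved volume of {x : field(x) > level} for each level.

    The nodal field is interpolated linearly inside each triangle; triangles
    straddling a level are clipped at the iso-line.
    """
    levels = np.atleast_1d(np.asarray(levels, dtype=float))
    vals = nodal[tris]
    p = points[tris]
    areas = 0.5 * _cross2(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    rbar_a = areas * p[:, :, 0].mean(axis=1)
    vmin = vals.min(axis=1)
    vmax = vals.max(axis=1)

    # fully-above contribution via a descending cumulative sum over vmin
    order = np.argsort(-vmin)
    csum = np.concatenate([[0.0], np.cumsum(rbar_a[order])])
    n_above = np.searchsorted(-vmin[order], -levels, side="right")
    full = csum[n_above]

    out = np.empty(len(levels))
    for i, lev in enumerate(levels):
        sel = np.nonzero((vmin <= lev) & (vmax > lev))[0]
        if len(sel) == 0:
            out[i] = full[i]
            continue
        v = vals[sel] - lev
        q = p[sel]
        pos = v > 0
        npos = pos.sum(axis=1)

        acc = 0.0
        one = np.nonzero(npos == 1)[0]
        if len(one):
            ip = np.argmax(pos[one], axis=1)
            i1 = (ip + 1) % 3
            i2 = (ip + 2) % 3
            rows = np.arange(len(one))
            P = q[one][rows, ip]
            N1 = q[one][rows, i1]
            N2 = q[one][rows, i2]
            dP = v[one][rows, ip]
            d1 = v[one][rows, i1]
            d2 = v[one][rows, i2]
            X1 = P + (dP / (dP - d1))[:, None] * (N1 - P)
            X2 = P + (dP / (dP - d2))[:, None] * (N2 - P)
            acc += _tri_r_integral(P, X1, X2).sum()
        two = np.nonzero(npos == 2)[0]
        if len(two):
            im = np.argmin(pos[two], axis=1)
            i1 = (im + 1) % 3
            i2 = (im + 2) % 3
            rows = np.arange(len(two))
            N = q[two][rows, im]
            P1 = q[two][rows, i1]
            P2 = q[two][rows, i2]
            dN = v[two][rows, im]
            d1 = v[two][rows, i1]
            d2 = v[two][rows, i2]
            X1 = P1 + (d1 / (d1 - dN))[:, None] * (N - P1)
            X2 = P2 + (d2 / (d2 - dN))[:, None] * (N - P2)
            acc += _tri_r_integral(P1, P2, X2).sum()
            acc += _tri_r_integral(P1, X2, X1).sum()
        out[i] = full[i] + acc
    return 2.0 * np.pi * out


def superlevel_extent(points: np.ndarray, edges: np.ndarray,
                      nodal: np.ndarray, level: float):
    """Bounding extent of the super-level set {field >= level}.

    Returns ``(z_min, z_max, r_max)`` over nodes above the level and the
    linear crossings along mesh edges, or ``None`` for an empty set.
    """
    above = nodal >= level
    rs = [points[above, 0]]
    zs = [points[above, 1]]
    d0 = nodal[edges[:, 0]] - level
    d1 = nodal[edges[:, 1]] - level
    cross = (d0 > 0) != (d1 > 0)
    if cross.any():
        t = d0[cross] / (d0[cross] - d1[cross])
        x = points[edges[cross, 0]] + t[:, None] * (
            points[edges[cross, 1]] - points[edges[cross, 0]])
        rs.append(x[:, 0])
        zs.append(x[:, 1])
    rs = np.concatenate(rs)
    zs = np.concatenate(zs)
    if len(rs) == 0:
        return None
    return float(zs.min()), float(zs.max()), float(rs.max())
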