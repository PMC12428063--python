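"""Axisymmetric problem geometry: needle applicator, tissue domain, boundary tags.

All lengths are in centimetres.  The computational domain is the meridian
half-plane (r, z) of a tissue cylinder with the needle applicator inserted
along the symmetry axis from the top surface.  z runs from 0 (bottom face,
where the grounding pad sits) to ``domain_length`` (tissue surface).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# Boundary tags of the meshed tissue region.  Exactly one of the first five
# is assigned to every boundary edge; CHANNEL names the cooled subset of the
# needle wall (the internal coolant channel collapsed onto the wall, see
# docs/methods.md) and is exposed separately because it overlaps the
# ELECTRODE/INSULATION electric tags.
ELECTRODE = "ELECTRODE"
INSULATION = "INSULATION"
PAD = "PAD"
FARFIELD = "FARFIELD"
AXIS = "AXIS"
CHANNEL = "CHANNEL"

ELECTRIC_TAGS = (ELECTRODE, INSULATION, PAD, FARFIELD, AXIS)


class GeometryError(ValueError):
    """A geometric invariant is violated; the message names the constraint."""


@dataclass(frozen=True)
class ApplicatorGeometry:
    """Internally cooled needle electrode.

    Parameters
    ----------
    shaft_radius:
        Outer radius of the stainless tube (cm).
    channel_radius:
        Radius of the internal coolant channel (cm).  Not meshed; the
        coolant boundary condition is applied on the shaft wall.
    insulation_thickness:
        Thickness of the polyimide sheath covering the shaft above the
        exposed electrode (cm).
    exposure_length:
        Length of the uninsulated (energised) distal segment (cm).
    uncooled_tip_length:
        Distal length of the electrode that the coolant channel does not
        reach (cm).
    insertion_depth:
        Depth of the needle tip below the tissue surface (cm).
    """

    shaft_radius: float = 0.08255
    channel_radius: float = 0.0228
    insulation_thickness: float = 0.02032
    exposure_length: float = 1.5
    uncooled_tip_length: float = 0.5
    insertion_depth: float = 10.0

    def __post_init__(self) -> None:
        if not self.exposure_length > 0:
            raise GeometryError("exposure_length > 0")
        if not self.channel_radius < self.shaft_radius:
            raise GeometryError("channel_radius < shaft_radius")
        if not self.insulation_thickness >= 0:
            raise GeometryError("insulation_thickness >= 0")
        if not self.uncooled_tip_length >= 0:
            raise GeometryError("uncooled_tip_length >= 0")
        if not self.insertion_depth > self.exposure_length:
            raise GeometryError("insertion_depth > exposure_length")
        if not self.uncooled_tip_length <= self.insertion_depth:
            raise GeometryError("uncooled_tip_length <= insertion_depth")

    @property
    def insulated_radius(self) -> float:
        return self.shaft_radius + self.insulation_thickness


@dataclass(frozen=True)
class DomainGeometry:
    """Tissue cylinder with a grounding pad on the bottom face.

    The pad is represented as a grounded disc of ``pad_radius`` on the
    bottom boundary; ``pad_height`` is retained for completeness but the
    0.2 cm tall pad body is not meshed (its effect ~35 cm from the
    electrode is negligible).
    """

    domain_length: float = 45.0
    domain_radius: float = 45.0
    pad_radius: float = 7.6
    pad_height: float = 0.2

    def __post_init__(self) -> None:
        if not self.pad_radius < self.domain_radius:
            raise GeometryError("pad_radius < domain_radius")
        if not (self.domain_length > 0 and self.domain_radius > 0):
            raise GeometryError("domain dimensions > 0")

    @property
    def pad_area(self) -> float:
        """Pad contact area (cm^2)."""
        return float(np.pi * self.pad_radius**2)


@dataclass(frozen=True)
class ProblemGeometry:
    """Applicator placed in the domain, with derived axial stations.

    ``z_tip`` is the needle tip, ``z_junction`` the insulation/electrode
    interface (also the temperature-probe location on the shaft wall) and
    ``z_cooled`` the lowest cooled point of the shaft wall.
    """

    applicator: ApplicatorGeometry
    domain: DomainGeometry

    def __post_init__(self) -> None:
        a, d = self.applicator, self.domain
        if not a.insertion_depth < d.domain_length:
            raise GeometryError("insertion_depth < domain_length")
        if not a.insulated_radius < d.domain_radius:
            raise GeometryError("applicator inside domain")

    @property
    def z_top(self) -> float:
        return self.domain.domain_length

    @property
    def z_tip(self) -> float:
        return self.domain.domain_length - self.applicator.insertion_depth

    @property
    def z_junction(self) -> float:
        return self.z_tip + self.applicator.exposure_length

    @property
    def z_cooled(self) -> float:
        return self.z_tip + self.applicator.uncooled_tip_length

    @property
    def probe_location(self) -> tuple[float, float]:
        """Insulation/electrode interface on the shaft wall, (r, z) in cm."""
        return (self.applicator.shaft_radius, self.z_junction)

    def needle_radius_at(self, z: np.ndarray) -> np.ndarray:
        """Outer radius of the needle cut-out at height z (0 below the tip)."""
        z = np.asarray(z, dtype=float)
        r = np.where(z <= self.z_junction,
                     self.applicator.shaft_radius,
                     self.applicator.insulated_radius)
        return np.where(z < self.z_tip, 0.0, r)

    def cross_section_area(self) -> float:
        """Analytic (r, z) meridian area of the meshed tissue region (cm^2)."""
        a, d = self.applicator, self.domain
        full = d.domain_length * d.domain_radius
        needle = (a.exposure_length * a.shaft_radius
                  + (self.z_top - self.z_junction) * a.insulated_radius)
        return full - needle

    def tissue_volume(self) -> float:
        """Analytic revolved tissue volume (cm^3)."""
        a, d = self.applicator, self.domain
        full = np.pi * d.domain_radius**2 * d.domain_length
        needle = np.pi * (a.shaft_radius**2 * a.exposure_length
                          + a.insulated_radius**2 * (self.z_top - self.z_junction))
        return float(full - needle)

    def electrode_segments(self) -> list[tuple[tuple[float, float], tuple[float, float]]]:
        """The energised surface: exposed shaft wall plus the flat tip face."""
        a = self.applicator
        return [
            ((a.shaft_radius, self.z_tip), (a.shaft_radius, self.z_junction)),
            ((0.0, self.z_tip), (a.shaft_radius, self.z_tip)),
        ]

    def distance_to_electrode(self, points: np.ndarray) -> np.ndarray:
        """Distance from (n, 2) points to the energised surface."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        dmin = np.full(len(pts), np.inf)
        for (p0, p1) in self.electrode_segments():
            p0 = np.asarray(p0)
            v = np.asarray(p1) - p0
            t = np.clip(((pts - p0) @ v) / (v @ v), 0.0, 1.0)
            proj = p0 + t[:, None] * v
            dmin = np.minimum(dmin, np.hypot(*(pts - proj).T))
        return dmin

    def classify_boundary_edges(self, midpoints: np.ndarray, tol: float = 1e-9) -> np.ndarray:
        """Assign exactly one electric tag to each boundary-edge midpoint.

        Raises :class:`GeometryError` if any midpoint does not lie on a
        recognised geometric feature (an untagged boundary would make the
        electrostatic problem ill-posed).
        """
        a, d = self.applicator, self.domain
        rm = midpoints[:, 0]
        zm = midpoints[:, 1]
        tags = np.empty(len(midpoints), dtype=object)
        tags[:] = None

        on_axis = rm < tol
        on_bottom = np.abs(zm) < tol
        on_top = np.abs(zm - self.z_top) < tol
        on_outer = np.abs(rm - d.domain_radius) < tol
        on_shaft = np.abs(rm - a.shaft_radius) < tol
        on_insul = np.abs(rm - a.insulated_radius) < tol
        on_tipface = np.abs(zm - self.z_tip) < tol
        on_step = np.abs(zm - self.z_junction) < tol

        tags[on_axis] = AXIS
        tags[on_bottom & (rm <= d.pad_radius + tol)] = PAD
        tags[on_bottom & (rm > d.pad_radius + tol)] = FARFIELD
        tags[on_outer] = FARFIELD
        tags[on_top & (rm > a.insulated_radius - tol)] = FARFIELD
        # needle wall
        exposed = on_shaft & (zm >= self.z_tip - tol) & (zm <= self.z_junction + tol)
        tags[exposed] = ELECTRODE
        tags[on_tipface & (rm <= a.shaft_radius + tol)] = ELECTRODE
        sheathed = on_insul & (zm >= self.z_junction - tol)
        tags[sheathed] = INSULATION
        step = on_step & (rm >= a.shaft_radius - tol) & (rm <= a.insulated_radius + tol)
        tags[step] = INSULATION

        if (tags == None).any():  # noqa: E711  (object-array comparison)
            bad = midpoints[tags == None][:5]  # noqa: E711
            raise GeometryError(f"untagged boundary edge midpoints near {bad.tolist()}")
        return tags.astype("U10")


def build_geometry(applicator: ApplicatorGeometry | None = None,
                   domain: DomainGeometry | None = None) -> ProblemGeometry:
    """Validate and assemble the tagged axisymmetric problem geometry."""
    return ProblemGeometry(applicator or ApplicatorGeometry(),
                           domain or DomainGeometry())
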