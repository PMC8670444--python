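"""Kinematic hemisphere-flattening model of fingertip compression.

When a fingertip is pressed on a flat plate, the quasihemispherical skin
surface inside the contact flattens into a disk.  Material that initially
lay along the spherical arc must fit onto the shorter chord, so the skin
is compressed (or, if friction lets it slip, it expands outward instead).
This module quantifies that purely geometric strain: no elasticity, no
pressure distribution — only the arc-versus-chord kinematics of a
spherical cap of radius ``R`` indented by a depth ``delta``.

With contact half-angle ``theta = arccos(1 - delta/R)``, the flattened
cap has chord half-length ``a = R sin(theta)`` while the original
meridional arc length is ``s = R theta``.  The meridional compressive
strain is ``1 - sin(theta)/theta``; for a typical fingertip (R = 10 mm)
indented by 3 mm this is about 10 %.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DomainError

__all__ = [
    "HemisphereGeometry",
    "compressive_strain",
    "hoop_strain",
    "contact_radius",
]

#: Default fingertip radius in mm (typical adult index distal phalanx).
DEFAULT_FINGER_RADIUS_MM = 10.0


@dataclass(frozen=True)
class HemisphereGeometry:
    """A spherical fingertip cap pressed a given depth into a flat plate.

    Parameters
    ----------
    radius : float
        Radius of the undeformed quasihemispherical fingertip, mm.
    indentation : float
        Normal indentation depth of the plate into the sphere, mm.
        Must satisfy ``0 <= indentation < radius``.
    """

    radius: float = DEFAULT_FINGER_RADIUS_MM
    indentation: float = 0.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.radius) and self.radius > 0):
            raise DomainError(f"radius must be positive and finite, got {self.radius}")
        if not math.isfinite(self.indentation) or self.indentation < 0:
            raise DomainError(
                f"indentation must be non-negative and finite, got {self.indentation}"
            )
        if self.indentation >= self.radius:
            raise DomainError(
                f"indentation ({self.indentation}) must be smaller than the "
                f"radius ({self.radius}); the cap model breaks down at full "
                "engulfment"
            )

    @property
    def contact_half_angle(self) -> float:
        """Polar half-angle of the flattened cap, rad."""
        return math.acos(1.0 - self.indentation / self.radius)


def compressive_strain(geom: HemisphereGeometry) -> float:
    """Meridional compressive strain of the flattened spherical cap.

    The arc of length ``R*theta`` is compressed onto the chord of length
    ``R*sin(theta)``; the strain is ``1 - sin(theta)/theta`` and lies in
    ``[0, 1)``.  For small indentation it behaves as
    ``theta**2/6 ~ indentation/(3*radius)``.
    """
    theta = geom.contact_half_angle
    if theta == 0.0:
        return 0.0
    return 1.0 - math.sin(theta) / theta


def hoop_strain(geom: HemisphereGeometry) -> float:
    """Azimuthal (hoop) strain at the edge of the flattened cap.

    Under the arc-preserving flattening map, material initially on the
    circle of circumference ``2*pi*R*sin(theta)`` is carried to planar
    radius ``R*theta``, a hoop *stretch*; the compressive hoop strain of
    the inverse (chord-preserving) convention equals the meridional
    value.  We report the latter so both measures share a sign
    convention; for this kinematic map they coincide at the cap edge.
    """
    return compressive_strain(geom)


def contact_radius(geom: HemisphereGeometry) -> float:
    """Radius of the circular contact footprint, mm.

    ``a = sqrt(R**2 - (R - delta)**2)``, monotone increasing in the
    indentation ``delta`` and Hertz-like (``a ~ sqrt(2*R*delta)``) for
    shallow indentation.
    """
    h = geom.radius - geom.indentation
    return math.sqrt(max(geom.radius**2 - h**2, 0.0))
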