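"""Geometry of the semicircular-canal duct.

The membranous duct is modelled as a planar circular arc of major radius
``R`` and slender-duct radius ``a``.  Positions along the duct are measured
by the arc coordinate ``psi`` in degrees, with ``psi = 0`` at the ampulla
end and ``psi = duct_span_deg`` at the utricle opening.  In the upright
position the ampulla sits a fixed elevation angle below the horizontal, so
the gravitationally lowest point of the duct lies ``90 - elevation``
degrees away from the ampulla.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InvalidParameterError


@dataclass(frozen=True)
class CanalGeometry:
    """Planar circular duct with an ampulla end and a utricle end.

    Parameters
    ----------
    major_radius:
        Radius ``R`` of the duct centreline circle, in metres.
    duct_radius:
        Inner radius ``a`` of the slender duct, in metres.  Must be small
        compared to ``major_radius`` (slender-duct assumption).
    duct_span_deg:
        Angular extent of the duct from the ampulla (``psi = 0``) to the
        utricle opening, in degrees.  Must lie in (180, 360).
    upright_ampulla_elevation_deg:
        Angle between the horizontal and the ampulla in the upright
        position, in degrees.
    """

    major_radius: float = 16e-3
    duct_radius: float = 0.75e-3
    duct_span_deg: float = 240.0
    upright_ampulla_elevation_deg: float = 32.0

    def __post_init__(self) -> None:
        if not self.major_radius > 0:
            raise InvalidParameterError("major_radius must be positive")
        if not 0 < self.duct_radius < self.major_radius:
            raise InvalidParameterError(
                "duct_radius must be positive and smaller than major_radius"
            )
        if not 180.0 < self.duct_span_deg < 360.0:
            raise InvalidParameterError(
                f"duct_span_deg must lie in (180, 360), got {self.duct_span_deg}"
            )
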