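"""Dynamic-similarity scaling between a scaled bench canal model and the human organ.

A bench model that is geometrically ``f`` times larger than the human
semicircular canal behaves on the same time base as the organ if

* the working fluid's kinematic viscosity is ``f**2`` times the endolymph
  viscosity, and
* the particle-to-fluid density ratio is ``1 + f * (rho_p/rho - 1)``,
  where ``rho_p/rho`` is the otoconia-to-endolymph density ratio.

This module encodes those similarity rules, the Stokes settling velocity
that drives every particle-size argument, and the conversion of a scaled
model specification back to human-scale parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .errors import InvalidParameterError, PairingError
from .geometry import CanalGeometry

#: Standard gravitational acceleration, m/s^2.
G_STANDARD = 9.81

REGIMES = ("scaled_model", "human")


@dataclass(frozen=True)
class MaterialSpec:
    """Fluid + particle material pair, in SI units.

    ``regime`` labels whether the values describe the scaled bench model
    or the human canal; it is metadata used to guard scaling operations.
    """

    fluid_kinematic_viscosity: float  # m^2/s
    fluid_density: float  # kg/m^3
    particle_diameter: float  # m
    particle_density: float  # kg/m^3
    regime: str = "scaled_model"

    def __post_init__(self) -> None:
        for name in (
            "fluid_kinematic_viscosity",
            "fluid_density",
            "particle_diameter",
            "particle_density",
        ):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be strictly positive")
        if self.particle_density < self.fluid_density:
            raise InvalidParameterError(
                "particle_density must be >= fluid_density "
                "(a buoyant particle never settles)"
            )
        if self.regime not in REGIMES:
            raise InvalidParameterError(
                f"regime must be one of {REGIMES}, got {self.regime!r}"
            )

    @property
    def density_ratio(self) -> float:
        """Particle-to-fluid density ratio rho_p / rho_e."""
        return self.particle_density / self.fluid_density


@dataclass(frozen=True)
class ScalingSpec:
    """Geometric scaling factor and the human reference densities."""

    geometric_factor: float = 5.0
    reference_endolymph_density: float = 1000.0  # kg/m^3
    reference_otoconia_density: float = 2700.0  # kg/m^3

    def __post_init__(self) -> None:
        if not self.geometric_factor >= 1.0:
            raise InvalidParameterError("geometric_factor must be >= 1")
        if not self.reference_endolymph_density > 0:
            raise InvalidParameterError("reference_endolymph_density must be positive")
        if not self.reference_otoconia_density > 0:
            raise InvalidParameterError("reference_otoconia_density must be positive")


def required_viscosity_factor(geometric_factor: float) -> float:
    """Factor by which the model fluid viscosity must exceed endolymph viscosity.

    Matching the settling dynamics of a model scaled up by ``f`` on the
    original time base requires the kinematic viscosity to grow as ``f**2``.
    """
    if not geometric_factor > 0:
        raise InvalidParameterError("geometric_factor must be positive")
    return geometric_factor**2


def required_density_ratio(geometric_factor: float, human_ratio: float) -> float:
    """Required model particle-to-fluid density ratio: ``1 + f * (r - 1)``.

    ``human_ratio`` is the otoconia-to-endolymph density ratio (about 2.7).
    Neutral buoyancy (``r = 1``) is a fixed point for every ``f``.
    """
    if not geometric_factor > 0:
        raise InvalidParameterError("geometric_factor must be positive")
    if human_ratio < 1.0:
        raise InvalidParameterError("human density ratio must be >= 1")
    return 1.0 + geometric_factor * (human_ratio - 1.0)


def unscale_model(
    materials: MaterialSpec,
    canal: CanalGeometry,
    scaling: ScalingSpec = ScalingSpec(),
) -> tuple[MaterialSpec, CanalGeometry]:
    """Convert a scaled-model specification to the corresponding human one.

    Lengths shrink by ``f``, viscosity by ``f**2``; the particle density is
    mapped through the similarity rule so that the human particle-to-fluid
    density ratio ``r`` satisfies ``1 + f*(r - 1) = rho_p_model/rho_e_model``.
    """
    if materials.regime != "scaled_model":
        raise InvalidParameterError("unscale_model expects a scaled_model spec")
    f = scaling.geometric_factor
    rho_ref = scaling.reference_endolymph_density
    human_ratio = 1.0 + (materials.density_ratio - 1.0) / f
    human_materials = MaterialSpec(
        fluid_kinematic_viscosity=materials.fluid_kinematic_viscosity / f**2,
        fluid_density=rho_ref,
        particle_diameter=materials.particle_diameter / f,
        particle_density=rho_ref * human_ratio,
        regime="human",
    )
    human_canal = replace(
        canal,
        major_radius=canal.major_radius / f,
        duct_radius=canal.duct_radius / f,
    )
    return human_materials, human_canal


def rescale_model(
    materials: MaterialSpec,
    canal: CanalGeometry,
    scaling: ScalingSpec,
    model_fluid_density: float,
) -> tuple[MaterialSpec, CanalGeometry]:
    """Inverse of :func:`unscale_model`.

    The bench fluid density is a free choice of the experimenter (only the
    density *ratio* is constrained by similarity), so it must be supplied.
    """
    if materials.regime != "human":
        raise InvalidParameterError("rescale_model expects a human spec")
    f = scaling.geometric_factor
    model_ratio = required_density_ratio(f, materials.density_ratio)
    model_materials = MaterialSpec(
        fluid_kinematic_viscosity=materials.fluid_kinematic_viscosity * f**2,
        fluid_density=model_fluid_density,
        particle_diameter=materials.particle_diameter * f,
        particle_density=model_fluid_density * model_ratio,
        regime="scaled_model",
    )
    model_canal = replace(
        canal,
        major_radius=canal.major_radius * f,
        duct_radius=canal.duct_radius * f,
    )
    return model_materials, model_canal


def settling_velocity(
    spec: MaterialSpec,
    drag_correction: float = 1.0,
    gravity_magnitude: float = G_STANDARD,
) -> float:
    """Stokes terminal settling velocity of the particle, in m/s.

    ``v_s = (rho_p - rho_e) * g * D**2 / (18 * rho_e * nu * lambda)``

    ``drag_correction`` (lambda >= 1) accounts for the extra drag on a
    particle settling along the duct wall; 1 recovers free-Stokes drag.
    The velocity is exactly quadratic in the particle diameter, which is
    why halving the diameter quadruples every settling time.
    """
    if drag_correction < 1.0:
        raise InvalidParameterError("drag_correction must be >= 1")
    if not gravity_magnitude > 0:
        raise InvalidParameterError("gravity_magnitude must be positive")
    rho_e = spec.fluid_density
    excess = spec.particle_density - rho_e
    return (
        excess
        * gravity_magnitude
        * spec.particle_diameter**2
        / (18.0 * rho_e * spec.fluid_kinematic_viscosity * drag_correction)
    )


def model_to_human_settling_slowdown(
    model: MaterialSpec,
    human: MaterialSpec,
    drag_correction: float = 1.0,
) -> float:
    """Ratio of model to human settling times over corresponding distances.

    The model particle covers a distance ``f`` times longer at its own
    Stokes velocity, so the ratio equals ``f * v_human / v_model`` and is
    independent of the distance chosen.  A ratio above 1 means the bench
    model settles more slowly than the human organ, i.e. its predicted
    critical times are conservative.
    """
    f = model.particle_diameter / human.particle_diameter
    if f < 1.0 or not math.isfinite(f):
        raise PairingError(
            "model particle diameter must be the human diameter times the "
            f"geometric factor (got ratio {f:.3g})"
        )
    v_model = settling_velocity(model, drag_correction)
    v_human = settling_velocity(human, drag_correction)
    if v_human == 0.0 or v_model == 0.0:
        raise PairingError("settling slowdown undefined for neutrally buoyant specs")
    return f * v_human / v_model
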