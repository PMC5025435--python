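import pytest
from hypothesis import settings

from canalith import CanalGeometry, ManeuverSpec, MaterialSpec, calibrate_drag

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def canal():
    """Bench canal geometry: R = 16 mm, a = 0.75 mm, ampulla 32 deg below horizontal."""
    return CanalGeometry()


@pytest.fixture(scope="session")
def model_materials():
    """Scaled-model materials: viscous fluid + 250 um steel microsphere."""
    return MaterialSpec(
        fluid_kinematic_viscosity=27e-6,
        fluid_density=945.0,
        particle_diameter=250e-6,
        particle_density=7800.0,
        regime="scaled_model",
    )


@pytest.fixture(scope="session")
def human_materials():
    """Human-regime materials: endolymph + 50 um otoconium."""
    return MaterialSpec(
        fluid_kinematic_viscosity=1e-6,
        fluid_density=1000.0,
        particle_diameter=50e-6,
        particle_density=2700.0,
        regime="human",
    )


@pytest.fixture(scope="session")
def maneuver_template():
    """Stepper maneuver template; the resting time is substituted by scans.

    The long final observation window costs nothing (constant-orientation
    phases are propagated in closed form) and guarantees decided outcomes
    arbitrarily close to the critical resting time.
    """
    return ManeuverSpec(
        extension_angle_deg=20.0,
        maneuver_velocity_deg_s=90.0,
        resting_time_s=5.0,
        final_observation_s=600.0,
    )


@pytest.fixture(scope="session")
def drag_lambda(canal, model_materials, maneuver_template):
    """Wall-drag correction calibrated once on the 30 deg / 90 deg/s cell."""
    return calibrate_drag(canal, model_materials, maneuver_template)
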