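import numpy as np
import pytest

from kneeprop.synthetic import GeneratorConfig, template_knee_cycle


@pytest.fixture(scope="session")
def default_template():
    """Template cycle with the small varus/rotation offsets."""
    return template_knee_cycle(GeneratorConfig())


@pytest.fixture(scope="session")
def hinge_template():
    """Pure-hinge template: flexion only, no varus/rotation offsets."""
    return template_knee_cycle(
        GeneratorConfig(varus_offset_deg=0.0, rotation_offset_deg=0.0))


def random_rotation(rng: np.random.Generator,
                    theta_range=(1.0, 179.0)) -> np.ndarray:
    """Uniform random axis, angle in the given degree range."""
    from kneeprop.kinematics import rotation_from_attitude

    v = rng.standard_normal(3)
    v /= np.linalg.norm(v)
    theta = rng.uniform(*theta_range)
    return rotation_from_attitude(theta, v)


def random_knee_pose(rng: np.random.Generator):
    """A random non-degenerate ParameterVector respecting the knee
    sign convention, with margins away from the domain boundary."""
    from kneeprop.uncertainty import ParameterVector

    def disk(radius):
        r = radius * np.sqrt(rng.uniform())
        a = rng.uniform(0, 2 * np.pi)
        return r * np.cos(a), r * np.sin(a)

    kx, ky = disk(0.6)
    e1x, e1y = disk(0.4)
    e3x, e3z = disk(0.6)
    return ParameterVector(rng.uniform(5.0, 170.0), kx, ky, e1x, e1y, e3x, e3z)
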