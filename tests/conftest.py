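import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_field_2d():
    """Small homogeneous 2-D two-wire solve shared across tests."""
    from ablaquant import field as F

    domain = F.TissueDomain(((-6.0, 6.0), (-6.0, 6.0)),
                            (F.Region("full", 0.5, "bg"),),
                            grid_step_mm=0.1, dimensionality=2)
    electrodes = F.ElectrodePair(spacing_mm=2.0, diameter_mm=0.4,
                                 exposure_mm=2.0, applied_voltage_v=300.0)
    return F.solve_field(domain, electrodes), domain, electrodes


@pytest.fixture(scope="session")
def small_field_3d():
    from ablaquant import field as F

    domain = F.TissueDomain(((-6.0, 6.0),) * 3,
                            (F.Region("full", 0.5, "bg"),
                             F.Region("sphere", 0.5, "tumor",
                                      center_mm=(0.0, 0.0, 0.0),
                                      radius_mm=1.5)),
                            grid_step_mm=0.2, dimensionality=3)
    electrodes = F.ElectrodePair(spacing_mm=2.0, diameter_mm=0.4,
                                 exposure_mm=2.0, applied_voltage_v=300.0)
    return F.solve_field(domain, electrodes), domain, electrodes
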