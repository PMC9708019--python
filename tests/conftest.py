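import numpy as np
import pytest

import tavica
from tavica.geometry import AnnularPlane, AorticRootGeometry, Landmarks


@pytest.fixture
def plane():
    """Canonical annular plane: origin at 0, normal toward the aorta (-z)."""
    return AnnularPlane(origin=np.zeros(3), normal=np.array([0.0, 0.0, -1.0]))


@pytest.fixture
def cylinder():
    return AorticRootGeometry.cylinder(12.0)


@pytest.fixture
def ibms_landmarks():
    """IBMS at the annular level spanning 30 deg of a 12 mm cylinder."""
    r = 12.0
    return Landmarks(
        p1=np.array([r, 0.0, 0.0]),
        p3=np.array([r * np.cos(np.radians(30)), r * np.sin(np.radians(30)), 0.0]),
        rcc_reference_angle=90.0,
    )


@pytest.fixture(scope="session")
def calibration():
    return tavica.default_calibration()


@pytest.fixture(scope="session")
def fixture_cohort():
    return tavica.fixture_cohort_from_table1()


@pytest.fixture(scope="session")
def small_cohort():
    """A 400-patient statistical cohort for pipeline-level tests."""
    return tavica.sample_cohort_statistical(400, seed=7)
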