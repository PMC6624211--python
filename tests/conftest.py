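import numpy as np
import pytest

from koalasight.grid import PointPattern, Raster, StudyWindow
from koalasight.synthetic import SimulationScenario, generate_scenario_data


@pytest.fixture(scope="session")
def window10() -> StudyWindow:
    return StudyWindow(10.0, 10.0)


@pytest.fixture(scope="session")
def ramp_raster(window10) -> Raster:
    """Covariate Z(u) = x on the 10x10 window (smooth, analytic)."""
    xx, _ = window10.cell_centers()
    return Raster(values=xx.astype(float), cellsize=1.0, feature_class="ramp_x")


@pytest.fixture(scope="session")
def default_scenario_data():
    """One realisation of the default synthetic study system.

    Session-scoped: several modules exercise different stages of the
    same realisation.
    """
    return generate_scenario_data(SimulationScenario(seed=123))


@pytest.fixture()
def small_pattern(window10) -> PointPattern:
    rng = np.random.default_rng(7)
    return PointPattern(
        rng.uniform(0, 10, 200), rng.uniform(0, 10, 200), window10
    )
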