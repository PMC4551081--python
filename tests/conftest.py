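import numpy as np
import pytest

from usem.data_model import RoiTimeSeries, center
from usem.synthesis import second_order_scenario, simulate_usem


@pytest.fixture(scope="session")
def scen_series():
    """One centered realization of the canonical 3-ROI second-order scenario."""
    return center(simulate_usem(second_order_scenario(seed=7)))


@pytest.fixture(scope="session")
def scen_truth():
    return {pid for pid, _ in second_order_scenario().nonzero_coefficients()}


@pytest.fixture()
def white_series():
    rng = np.random.default_rng(123)
    return center(RoiTimeSeries(rng.standard_normal((3, 300)), ("A", "B", "C")))
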