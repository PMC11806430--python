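import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import gaconcord as g

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_grid() -> g.TestGrid:
    return g.build_t_grid()


@pytest.fixture(scope="session")
def noiseless_render() -> g.RenderConfig:
    return g.RenderConfig(noise="none")


@pytest.fixture(scope="session")
def concordant_phantom() -> g.Phantom:
    return g.make_phantom(g.scenario_preset("concordant"), seed=1)


@pytest.fixture(scope="session")
def noiseless_scan(concordant_phantom, noiseless_render) -> g.LineScan:
    return g.render_line_scan(concordant_phantom, "horizontal", noiseless_render)
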