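import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from ocphot import synthetic  # noqa: E402


@pytest.fixture(scope="session")
def coarse_grid():
    """Coarse wavenumber grid keeping the fit-heavy tests fast."""
    return np.arange(14000.0, 24000.0, 50.0)


@pytest.fixture(scope="session")
def species_basis(coarse_grid):
    presets = synthetic.ocp_species_presets()
    return [
        synthetic.make_vibronic_spectrum(presets[name], coarse_grid)
        for name in ("OCPO", "OCPI", "OCPR")
    ]


@pytest.fixture(scope="session")
def two_scale_times():
    """Times resolving both a ~100 s and a ~500 s process."""
    return tuple(
        np.unique(
            np.concatenate([np.linspace(0.0, 300.0, 20), np.linspace(0.0, 2000.0, 20)])
        )
    )
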