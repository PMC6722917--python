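import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("reproducible", derandomize=True, deadline=None)
settings.load_profile("reproducible")

from fibermech import FiberLawParams, MembraneSpec
from fibermech.data import BLEND_LABELS, SFPCL_DIAMETERS, SFPCL_FIBER_FITS


@pytest.fixture(scope="session")
def blend_fits() -> dict[str, FiberLawParams]:
    return SFPCL_FIBER_FITS


@pytest.fixture(scope="session")
def blend_labels() -> tuple[str, ...]:
    return BLEND_LABELS


@pytest.fixture(scope="session")
def blend_diameters() -> dict[str, tuple[float, float, float]]:
    return SFPCL_DIAMETERS


def make_spec(label: str = "100/0", *, porosity: float = 0.85,
              r0_nm: float = 5000.0, area_nm2: float = 1e6,
              shrinkage_v: float = 0.9) -> MembraneSpec:
    arithmetic, _, harmonic = SFPCL_DIAMETERS[label]
    return MembraneSpec(porosity=porosity, r0_nm=r0_nm, area_nm2=area_nm2,
                        harmonic_d_nm=harmonic, shrinkage_v=shrinkage_v,
                        arithmetic_d_nm=arithmetic)


@pytest.fixture
def spec() -> MembraneSpec:
    return make_spec()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
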