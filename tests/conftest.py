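import numpy as np
import pytest

from sypflux import ImagingParams, SCENARIOS
from sypflux.synthetic import GonadSpec, build_layout


@pytest.fixture(scope="session")
def imaging_clean() -> ImagingParams:
    return ImagingParams(noise="none")


@pytest.fixture(scope="session")
def imaging_noisy() -> ImagingParams:
    return ImagingParams(noise="poisson_gaussian")


@pytest.fixture(scope="session")
def small_spec() -> GonadSpec:
    """A short gonad used by tests that only need a handful of nuclei."""
    return GonadSpec(n_rows=6, nuclei_per_row=1)


@pytest.fixture(scope="session")
def mid_nucleus(small_spec):
    """One mid-pachytene nucleus with fixed kinetics (f=0.5, k=0.1/min)."""
    layout = build_layout(small_spec, SCENARIOS["wt"], seed=42, stages=("mid",))
    nuc = layout.nuclei[0]
    nuc.mobile_fraction_f = 0.5
    nuc.exchange_rate_k = 0.1
    return nuc


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
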