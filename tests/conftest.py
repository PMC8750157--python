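import numpy as np
import pytest

from mpfi.core_io import AcquisitionMeta
from mpfi.dce import PopulationAIF


@pytest.fixture(scope="session")
def meta() -> AcquisitionMeta:
    return AcquisitionMeta()


@pytest.fixture(scope="session")
def aif(meta) -> PopulationAIF:
    """Population AIF with bolus arrival at the end of the baseline frames."""
    return PopulationAIF(bolus_arrival_s=meta.n_baseline_frames * meta.frame_duration_s)


@pytest.fixture(scope="session")
def frame_times(meta) -> np.ndarray:
    return np.arange(75) * meta.frame_duration_s


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)
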