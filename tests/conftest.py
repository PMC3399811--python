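import numpy as np
import pytest

from tagcna.io_formats import MarkerMap
from tagcna.segmentation import cbs_segment


@pytest.fixture(scope="session", autouse=True)
def _warm_kernels():
    # trigger the numba compilation once so individual timings stay honest
    cbs_segment(np.zeros(16))


@pytest.fixture
def rng():
    return np.random.default_rng(20120718)


def make_markers(n, chrom="chr1", spacing=1000):
    return MarkerMap(
        np.array([f"M{i + 1:06d}" for i in range(n)], dtype=object),
        np.array([chrom] * n, dtype=object),
        1 + spacing * np.arange(n, dtype=np.int64),
    )


@pytest.fixture
def markers10():
    return make_markers(10)
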