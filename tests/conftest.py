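import numpy as np
import pandas as pd
import pytest

import icimqei as q


@pytest.fixture(scope="session")
def benchmark_map():
    return q.standard_map()


@pytest.fixture(scope="session")
def unlinked():
    return q.unlinked_architecture()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_map():
    """Two chromosomes, 3 + 2 markers, uneven spacing."""
    return q.GeneticMap(pd.DataFrame({
        "marker": ["m1", "m2", "m3", "n1", "n2"],
        "chromosome": ["1", "1", "1", "2", "2"],
        "position_cM": [0.0, 12.0, 30.0, 0.0, 20.0],
    }))
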