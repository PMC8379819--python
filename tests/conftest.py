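import numpy as np
import pandas as pd
import pytest

from coexflow import preprocess as pp
from coexflow import synthetic_data as sd


@pytest.fixture(scope="session")
def benchmark():
    """Seed-1 benchmark fixture: design, metadata, counts, truth."""
    return sd.benchmark_dataset(seed=1)


@pytest.fixture(scope="session")
def benchmark_expr(benchmark):
    """VST expression matrix of the seed-1 benchmark fixture."""
    _, _, counts, _ = benchmark
    counts_f = pp.filter_low_expression(counts)
    sf = pp.size_factors(counts_f)
    trend = pp.fit_dispersion_trend(counts_f, sf)
    return pp.vst_transform(counts_f, sf, trend)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def toy_counts():
    """Small deterministic count matrix with a spread of row sums."""
    rng = np.random.default_rng(42)
    mat = rng.poisson(50, size=(20, 6))
    return pd.DataFrame(
        mat,
        index=[f"g{i}" for i in range(20)],
        columns=[f"s{j}" for j in range(6)],
    )
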