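import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from cariestrend import PrevalenceSeries, load_benchmark_series, load_holdout_actuals


@pytest.fixture(scope="session")
def benchmark() -> PrevalenceSeries:
    """Pooled national ECC prevalence 1988-2010 (23 annual values, percent)."""
    return load_benchmark_series()


@pytest.fixture(scope="session")
def holdout() -> PrevalenceSeries:
    """Holdout actuals 2011-2013."""
    return load_holdout_actuals()


@pytest.fixture(scope="session")
def full_series(benchmark, holdout) -> PrevalenceSeries:
    return benchmark.concat(holdout)
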