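import numpy as np
import pytest

from modseek.alignment import SearchParams
from modseek.simulate import make_wt_trna


@pytest.fixture(scope="session")
def params() -> SearchParams:
    """Default BLASTP-style search parameters (shared: matrix load is not free)."""
    return SearchParams()


@pytest.fixture(scope="session")
def wt_trna():
    """Unmodified synthetic wild-type tRNA transcript with its annotation."""
    return make_wt_trna(cm6=False)


@pytest.fixture(scope="session")
def cm6_trna():
    """The same transcript carrying the 2'-O-methyl at position 6."""
    return make_wt_trna(cm6=True)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
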