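import numpy as np
import pytest

from wadihsi.datasets import hajar_site_metrics
from wadihsi.synthetic import TrueModel, generate_sites


@pytest.fixture(scope="session")
def hajar():
    """Twelve-site published survey table (HSI + diversity metrics)."""
    return hajar_site_metrics()


@pytest.fixture(scope="session")
def survey12():
    """Default synthetic 12-site survey, fixed seed."""
    return generate_sites(TrueModel(seed=42), 12)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
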