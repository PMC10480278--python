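import numpy as np
import pytest

from phspec import ProtonationScheme


@pytest.fixture
def ph_grid():
    """The assay pH range 3-11 in 0.25 steps (33 points)."""
    return np.arange(3.0, 11.01, 0.25)


@pytest.fixture
def wt_scheme():
    """Four-pKa scheme with three active species (wild-type profile)."""
    return ProtonationScheme([4.4, 6.2, 7.6, 9.5], [0, 81.6, 106.8, 55.8, 0])


@pytest.fixture
def bell_scheme():
    """Two-pKa bell profile with a single active species."""
    return ProtonationScheme([4.6, 8.9], [0, 100.0, 0])
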