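import numpy as np
import pytest

from cytodose import tables
from cytodose.microdosimetry import PulseHeightSpectrum


@pytest.fixture(scope="session")
def dca_dists():
    """Pooled dicentric+ring distributions, six dose points."""
    return tables.dca_distributions()


@pytest.fixture(scope="session")
def mn_dists():
    """Pooled micronucleus distributions, six dose points."""
    return tables.mn_distributions()


def make_spectrum(midpoints, counts, particle="combined"):
    """Spectrum whose geometric bin midpoints are exactly the given values.

    Requires the midpoints to form a geometric sequence (constant ratio),
    so contiguous log-spaced edges e_i = m_i / s, e_{i+1} = m_i * s with
    s = sqrt(ratio) reproduce them exactly; a single midpoint uses s = 2.
    This lets tests assert closed-form moments without binning error.
    """
    m = np.asarray(midpoints, dtype=float)
    if m.size > 1:
        ratios = m[1:] / m[:-1]
        assert np.allclose(ratios, ratios[0]), "midpoints must be geometric"
        s = np.sqrt(ratios[0])
    else:
        s = 2.0
    edges = np.concatenate([[m[0] / s], m * s])
    return PulseHeightSpectrum(edges, np.asarray(counts, float), particle)


@pytest.fixture
def toy_spectrum():
    return make_spectrum([1.0, 5.0, 25.0, 125.0], [40.0, 30.0, 20.0, 10.0])
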