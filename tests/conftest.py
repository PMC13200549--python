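import numpy as np
import pytest

from flowalign import Spectrum


def random_spectrum(rng, n, dim=2, span=3.0, prefix="p"):
    """A random spectrum with positive intensities, for property tests."""
    return Spectrum(
        positions=rng.random((n, dim)) * span,
        intensities=rng.random(n) + 0.05,
        ids=tuple(f"{prefix}{i}" for i in range(n)),
        axes=tuple(f"axis{k}" for k in range(dim)),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def spectrum_pair_1d():
    """The two-peak spectra whose truncated transport cost is 7/3."""
    a = Spectrum(positions=[[0.0], [10.0]], intensities=[2.0, 1.0],
                 ids=("a0", "a1"), axes=("x",))
    b = Spectrum(positions=[[1.0], [30.0]], intensities=[2.0, 1.0],
                 ids=("b0", "b1"), axes=("x",))
    return a, b
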