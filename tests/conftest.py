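"""Shared fixtures: small Boltzmann conformer libraries and RNGs.

The conformer libraries are sampled once per session; their sizes are
chosen so the statistical error of every quantity asserted against them
is several times smaller than the asserted tolerance.
"""

import numpy as np
import pytest

from mesocat.gcmc import ConformerLibrary, sample_conformer_library


@pytest.fixture(scope="session")
def lib22() -> ConformerLibrary:
    """Boltzmann library of the 22-mer at its calibrated stiffness."""
    return sample_conformer_library(22, n_samples=1200, seed=7)


@pytest.fixture(scope="session")
def lib29() -> ConformerLibrary:
    """Boltzmann library of the 29-mer at its calibrated stiffness."""
    return sample_conformer_library(29, n_samples=700, seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
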