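import numpy as np
import pytest

from parvocone import (DEFAULT_GRID, OcularMedia, PigmentTemplate, Spectrum,
                       mean_background, synth_spectra)


@pytest.fixture(scope="session")
def grid():
    return DEFAULT_GRID


@pytest.fixture(scope="session")
def flat_illuminant(grid):
    return Spectrum(grid, np.ones(grid.n), role="illuminant", label="flat")


@pytest.fixture(scope="session")
def forest_illuminant():
    return synth_spectra("illuminant", 1, 7).targets[0]


@pytest.fixture(scope="session")
def fruit_library():
    lib = synth_spectra("fruit", 30, 42)
    leaves = synth_spectra("leaf", 60, 43)
    lib.background = mean_background(leaves)
    return lib


@pytest.fixture(scope="session")
def template():
    return PigmentTemplate()


@pytest.fixture(scope="session")
def media(grid):
    return OcularMedia.human(grid)


@pytest.fixture(scope="session")
def clear_media(grid):
    return OcularMedia.transparent(grid)
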