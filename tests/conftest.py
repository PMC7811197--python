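"""Shared fixtures: canonical phantoms are expensive, render once."""

import numpy as np
import pytest

from ribbonmetrics import phantom as ph
from ribbonmetrics.pipeline import canonical_lines


@pytest.fixture(scope="session")
def tight_identity():
    """Tight-configuration phantom, identity imaging, plus its truth."""
    grid, truth = ph.canonical_ribbon_phantom("tight", ph.ImagingModel())
    return grid, truth


@pytest.fixture(scope="session")
def loose_identity():
    grid, truth = ph.canonical_ribbon_phantom("loose", ph.ImagingModel())
    return grid, truth


@pytest.fixture(scope="session")
def fibril_identity():
    grid, truth = ph.canonical_ribbon_phantom("fibril", ph.ImagingModel())
    return grid, truth


@pytest.fixture(scope="session")
def width_identity():
    grid, truth = ph.canonical_ribbon_phantom("width", ph.ImagingModel())
    return grid, truth


@pytest.fixture(scope="session")
def tight_profile_line():
    return canonical_lines("tight")["profile"][0]


@pytest.fixture(scope="session")
def small_grid_rng():
    return np.random.default_rng(20260402)
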