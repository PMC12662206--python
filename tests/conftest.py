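import numpy as np
import pytest

from budoid_axis import (
    SimParams,
    extract_midline,
    make_organoid_mask,
    segment_structure,
    simulate_organoid,
)


@pytest.fixture(scope="session")
def straight_geometry():
    """Straight 400x100 capsule mask with its true midline."""
    return make_organoid_mask(SimParams(seed=1))


@pytest.fixture(scope="session")
def straight_structure(straight_geometry):
    """Segmented structure mask of the straight capsule."""
    return segment_structure(straight_geometry.mask.grid)


@pytest.fixture(scope="session")
def straight_midline(straight_structure):
    return extract_midline(straight_structure)


@pytest.fixture(scope="session")
def full_organoid():
    """Complete simulated organoid: strong gradient, 600 cells, Poisson noise."""
    return simulate_organoid(SimParams(seed=42))


@pytest.fixture(scope="session")
def true_reference(straight_geometry, straight_structure):
    """True midline of the straight capsule, shifted into the padded frame."""
    return straight_geometry.true_midline + np.array(straight_structure.pad_offset)
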