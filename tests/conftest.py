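import numpy as np
import pytest

from vmadapt import synthetic as syn
from vmadapt import task_design as td


@pytest.fixture(scope="session")
def session_design():
    return td.build_session(rng=np.random.default_rng(11))


@pytest.fixture(scope="session")
def small_grid():
    """Compact grid for fast searchlight tests; region boxes sit closer
    than the 9-mm searchlight radius, so cross-region spillover is expected
    and tests on this grid only assert within-region effects."""
    return syn.VolumeGrid((14, 14, 10))


@pytest.fixture(scope="session")
def study_grid():
    """Study-scale grid on which the four signal regions are separated by
    more than the searchlight radius."""
    return syn.VolumeGrid((24, 24, 18))


@pytest.fixture(scope="session")
def study_model(study_grid):
    return syn.PatternModel(grid=study_grid)


@pytest.fixture(scope="session")
def region_centers_mask(study_model):
    """Union of the four labeled regions: sphere centers for ROI-restricted
    searchlight runs."""
    masks = study_model.region_masks
    out = np.zeros(study_model.grid.dims, dtype=bool)
    for m in masks.values():
        out |= m
    return out
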