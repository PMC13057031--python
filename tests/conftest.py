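import numpy as np
import pytest

from mnscore.classify import ClassifierParams
from mnscore.segment import CellMask, SegmentationParams
from mnscore.simulate import SimulationConfig, simulate_field


@pytest.fixture
def seg_params():
    return SegmentationParams()


@pytest.fixture
def clf_params():
    return ClassifierParams()


@pytest.fixture(scope="session")
def fluor_field_and_truth():
    """A mid-size fluorescence field with all populations present."""
    cfg = SimulationConfig(
        n_cells_target=400, p_mn=0.03, p_multi_given_mn=0.2,
        wbc_fraction=0.01, platelet_fraction=0.02,
        overlap_fraction=0.0, seed=101)
    return simulate_field(cfg)


@pytest.fixture(scope="session")
def mgg_field_and_truth():
    cfg = SimulationConfig(
        modality="brightfield_mgg", n_cells_target=400, p_mn=0.05,
        ret_fraction=0.05, wbc_fraction=0.01, platelet_fraction=0.02,
        overlap_fraction=0.0, seed=102)
    return simulate_field(cfg)


def disc_mask(cy, cx, r_px, shape=(200, 200), pixel_size_um=0.25, cell_id=0):
    """A filled disc CellMask (test geometry helper)."""
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    m = np.hypot(yy - cy, xx - cx) <= r_px
    rr, cc = np.nonzero(m)
    return CellMask(cell_id, np.column_stack([rr, cc]), pixel_size_um, shape)


def fused_discs_mask(centers, r_px, shape=(200, 200), pixel_size_um=0.25):
    """Union of several discs as one CellMask (fused-cell fixture)."""
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    m = np.zeros(shape, bool)
    for cy, cx in centers:
        m |= np.hypot(yy - cy, xx - cx) <= r_px
    rr, cc = np.nonzero(m)
    return CellMask(0, np.column_stack([rr, cc]), pixel_size_um, shape)


def pixel_count_mask(n_px, pixel_size_um, shape=(200, 200), cell_id=0):
    """A compact mask with exactly n_px pixels (for size-filter boundaries)."""
    side = int(np.ceil(np.sqrt(n_px)))
    rows = np.repeat(np.arange(side), side)[:n_px] + 50
    cols = np.tile(np.arange(side), side)[:n_px] + 50
    return CellMask(cell_id, np.column_stack([rows, cols]), pixel_size_um, shape)
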