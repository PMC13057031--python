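"""Segmentation chain: thresholding, exclusion, separation, size filter."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import disc_mask, fused_discs_mask, pixel_count_mask
from mnscore.segment import (CellMask, SegmentationParams,
                             apply_exclusion_masks, filter_by_size,
                             segment_cell_bodies, separate_juxtaposed)
from mnscore.simulate import SimulationConfig, SmearField, simulate_field


def make_field(raster):
    return SmearField(raster=raster.astype(np.float32),
                      channels=("cell_body", "dna"), pixel_size_um=0.25)


class TestSegmentCellBodies:
    def test_single_disc_yields_one_mask_at_truth_centroid(self):
        cfg = SimulationConfig(n_cells_target=1, field_size_px=(128, 128),
                               p_mn=0, wbc_fraction=0, platelet_fraction=0,
                               seed=4)
        field, truth = simulate_field(cfg)
        masks = segment_cell_bodies(field, SegmentationParams())
        assert len(masks) == 1
        row = truth.records.iloc[0]
        cy, cx = masks[0].centroid
        assert abs(cy - row.y_px) <= 1.0
        assert abs(cx - row.x_px) <= 1.0

    def test_blank_field_gives_empty_list(self):
        rng = np.random.default_rng(0)
        raster = np.stack([np.full((128, 128), 0.05)
                           + rng.normal(0, 0.02, (128, 128))] * 2, axis=-1)
        assert segment_cell_bodies(make_field(raster),
                                   SegmentationParams()) == []

    def test_flat_field_gives_empty_list(self):
        raster = np.zeros((64, 64, 2))
        assert segment_cell_bodies(make_field(raster),
                                   SegmentationParams()) == []

    def test_component_count_matches_truth_on_sparse_field(self):
        cfg = SimulationConfig(n_cells_target=500, p_mn=0.01,
                               wbc_fraction=0, platelet_fraction=0,
                               overlap_fraction=0.0, seed=21)
        field, truth = simulate_field(cfg)
        masks = segment_cell_bodies(field, SegmentationParams())
        assert len(masks) == len(truth.records) == 500

    def test_masks_are_pairwise_disjoint(self, fluor_field_and_truth):
        field, _ = fluor_field_and_truth
        masks = segment_cell_bodies(field, SegmentationParams())
        canvas = np.zeros(field.raster.shape[:2], np.int32)
        for m in masks:
            canvas[m.pixels[:, 0], m.pixels[:, 1]] += 1
        assert canvas.max() == 1


class TestApplyExclusionMasks:
    def test_cell_inside_wbc_mask_removed(self):
        cell = disc_mask(100, 100, 10)
        wbc = disc_mask(100, 100, 20, cell_id=1)
        retained, removed = apply_exclusion_masks([cell], [wbc])
        assert retained == [] and removed == [cell]

    def test_no_exclusion_masks_is_identity(self):
        cell = disc_mask(100, 100, 10)
        retained, removed = apply_exclusion_masks([cell], [])
        assert retained == [cell] and removed == []

    def test_small_overlap_retained(self):
        # ~10% of the cell under a platelet mask -> kept
        cell = disc_mask(100, 100, 10)
        plt = disc_mask(100, 113, 5, cell_id=1)
        overlap = len({tuple(p) for p in cell.pixels}
                      & {tuple(p) for p in plt.pixels}) / cell.area_px
        assert overlap < 0.5
        retained, removed = apply_exclusion_masks([cell], [plt])
        assert retained == [cell]

    def test_majority_overlap_removed(self):
        cell = disc_mask(100, 100, 10)
        excl = disc_mask(100, 103, 10, cell_id=1)   # >50% covered
        retained, removed = apply_exclusion_masks([cell], [excl])
        assert removed == [cell]


class TestSeparateJuxtaposed:
    def test_two_fused_discs_split(self, seg_params):
        cm = fused_discs_mask([(100, 90), (100, 112)], 12)
        out, dropped = separate_juxtaposed([cm], seg_params, 0.25)
        assert dropped == 0
        assert len(out) == 2
        for mask, cx_true in zip(sorted(out, key=lambda m: m.centroid[1]),
                                 (90, 112)):
            assert abs(mask.centroid[0] - 100) <= 2
            assert abs(mask.centroid[1] - cx_true) <= 2

    def test_chain_of_three_split(self, seg_params):
        cm = fused_discs_mask([(100, 60), (100, 82), (100, 104)], 11)
        out, _ = separate_juxtaposed([cm], seg_params, 0.25)
        assert len(out) == 3

    def test_chain_of_four_split(self, seg_params):
        cm = fused_discs_mask([(100, 50), (100, 72), (100, 94), (100, 116)], 11)
        out, _ = separate_juxtaposed([cm], seg_params, 0.25)
        assert len(out) == 4

    def test_isolated_disc_roundtrip_preserves_area(self, seg_params):
        cm = disc_mask(100, 100, 12)
        out, dropped = separate_juxtaposed([cm], seg_params, 0.25)
        assert dropped == 0 and len(out) == 1
        assert abs(out[0].area_px - cm.area_px) / cm.area_px < 0.10

    def test_thin_mask_dropped_and_counted(self, seg_params):
        # a 3-px-wide sliver erodes to nothing under a 3-px disc
        rows = np.repeat(np.arange(50, 53), 30)
        cols = np.tile(np.arange(60, 90), 3)
        sliver = CellMask(0, np.column_stack([rows, cols]), 0.25, (200, 200))
        out, dropped = separate_juxtaposed([sliver], seg_params, 0.25)
        assert out == [] and dropped == 1

    def test_outputs_contained_in_parent_and_disjoint(self, seg_params):
        cm = fused_discs_mask([(100, 90), (100, 110), (118, 100)], 11)
        out, _ = separate_juxtaposed([cm], seg_params, 0.25)
        parent = {tuple(p) for p in cm.pixels}
        seen = set()
        for m in out:
            pix = {tuple(p) for p in m.pixels}
            assert pix <= parent          # containment
            assert not (pix & seen)       # disjointness
            seen |= pix


class TestFilterBySize:
    """Boundary semantics: the [7, 50] μm² interval is closed."""

    @pytest.mark.parametrize("n_px,pixel_size,expected", [
        (111, 0.25, "below"),     # 6.94 um^2 -> excluded (debris)
        (112, 0.25, "retained"),  # 7.00 um^2 -> retained (boundary)
        (800, 0.25, "retained"),  # 50.00 um^2 -> retained (boundary)
        (801, 0.25, "above"),     # 50.06 um^2 -> excluded (aggregate)
    ])
    def test_boundaries(self, n_px, pixel_size, expected, seg_params):
        cell = pixel_count_mask(n_px, pixel_size)
        retained, tally = filter_by_size([cell], seg_params)
        if expected == "retained":
            assert retained == [cell]
        else:
            assert retained == []
            assert tally[expected] == 1

    def test_border_touching_excluded_when_flagged(self, seg_params):
        cell = disc_mask(5, 100, 10, shape=(200, 200))  # touches row 0
        assert cell.border_touching
        retained, tally = filter_by_size([cell], seg_params)
        assert retained == [] and tally["border"] == 1
        lax = SegmentationParams(exclude_border_cells=False)
        retained2, _ = filter_by_size([cell], lax)
        assert retained2 == [cell]

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.lists(st.integers(min_value=20, max_value=6000),
                    min_size=1, max_size=12),
           st.floats(min_value=0.0, max_value=3.0),
           st.floats(min_value=0.0, max_value=20.0))
    def test_widening_interval_is_monotone(self, sizes, widen_lo, widen_hi):
        cells = [pixel_count_mask(n, 0.1, cell_id=i)
                 for i, n in enumerate(sizes)]
        tight = SegmentationParams(size_min_um2=7.0, size_max_um2=50.0)
        wide = SegmentationParams(size_min_um2=max(7.0 - widen_lo, 0.1),
                                  size_max_um2=50.0 + widen_hi)
        r_tight, _ = filter_by_size(cells, tight)
        r_wide, _ = filter_by_size(cells, wide)
        assert len(r_wide) >= len(r_tight)


class TestCellMaskGeometry:
    def test_disc_properties(self):
        cm = disc_mask(100, 100, 12)
        assert cm.aspect_ratio == pytest.approx(1.0, abs=0.05)
        assert cm.solidity > 0.93   # discrete disc vs its convex hull
        assert not cm.border_touching
        assert cm.equivalent_diameter_um == pytest.approx(
            2 * 12 * 0.25, rel=0.05)

    def test_empty_pixels_rejected(self):
        from mnscore.errors import ConfigError
        with pytest.raises(ConfigError):
            CellMask(0, np.empty((0, 2)), 0.25, (10, 10))
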