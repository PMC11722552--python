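import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage as ndi

from nervequant._util import iou
from nervequant.segmentation import (
    enhance_contrast_quantile,
    extract_soma,
    segment_cell_mask,
    segment_field,
    split_compartments,
    thickness_map,
)
from nervequant.synth import make_neuron_scene

from conftest import disk_mask

PX = 0.07  # µm per pixel used throughout


class TestContrastEnhancement:
    def test_constant_image_maps_to_zeros(self):
        out = enhance_contrast_quantile(np.full((16, 16), 7.0), 0.7)
        assert (out == 0).all()

    def test_ramp_anchors_match_sort_based_quantile(self):
        img = np.arange(256, dtype=float).reshape(16, 16)
        q = 0.7
        out = enhance_contrast_quantile(img, q)
        srt = np.sort(img.ravel())  # sort-based quantile oracle (linear interpolation)
        k = q * (img.size - 1)
        lo = srt[int(np.floor(k))] + (k - np.floor(k)) * (
            srt[int(np.ceil(k))] - srt[int(np.floor(k))]
        )
        assert ((out > 0) == (img > lo)).all()
        assert out.max() == pytest.approx(1.0)
        # linear between anchors
        mid = img[out > 0]
        assert np.allclose(out[out > 0], (mid - lo) / (img.max() - lo))

    def test_q_zero_is_minmax_rescale(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(10, 50, (20, 20))
        out = enhance_contrast_quantile(img, 0.0)
        assert np.allclose(out, (img - img.min()) / (img.max() - img.min()))

    @given(st.floats(min_value=0, max_value=0.99), st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_output_bounded_and_anchored(self, q, seed):
        img = np.random.default_rng(seed).uniform(0, 100, (12, 12))
        out = enhance_contrast_quantile(img, q)
        assert out.min() >= 0 and out.max() <= 1
        assert (out[img <= np.quantile(img, q)] == 0).all()


class TestCellMask:
    def test_blank_image_gives_empty_mask(self):
        assert not segment_cell_mask(np.zeros((32, 32)), PX).any()

    def test_small_object_removed_large_kept(self):
        # one ~10 µm² blob and one ~1 µm² speck at 0.07 µm/px
        img = np.zeros((200, 200))
        blob = disk_mask((200, 200), 60, 60, 25)     # ~1963 px ~ 9.6 µm²
        speck = disk_mask((200, 200), 150, 150, 8)   # ~201 px ~ 1.0 µm²
        img[blob] = 1.0
        img[speck] = 1.0
        mask = segment_cell_mask(img, PX)
        assert (mask & blob).sum() > 0.9 * blob.sum()
        assert not (mask & speck).any()

    def test_hole_handling_small_filled_large_kept(self):
        # 5 µm² hole (~1020 px -> r 18) filled; 30 µm² hole (~6122 px -> r 44) kept
        img = np.zeros((400, 400))
        body = disk_mask((400, 400), 200, 200, 150)
        small_hole = disk_mask((400, 400), 140, 140, 18)
        big_hole = disk_mask((400, 400), 250, 250, 44)
        img[body & ~small_hole & ~big_hole] = 1.0
        mask = segment_cell_mask(img, PX)
        assert mask[small_hole].all()
        # interior of the big hole stays background
        assert not mask[disk_mask((400, 400), 250, 250, 40)].any()


class TestThicknessMap:
    def test_disk_center_value_and_edt_agreement(self):
        disk = disk_mask((128, 128), 64, 64, 50)
        tm = thickness_map(disk)
        assert tm.distance[64, 64] == pytest.approx(50, abs=2)
        edt = ndi.distance_transform_edt(disk)
        dev = np.abs(tm.distance - edt)[disk]
        assert (dev <= 2).all()

    def test_bar_center_row_half_width(self):
        bar = np.zeros((61, 200), bool)
        bar[20:41, :] = True  # width 21 px
        tm = thickness_map(bar)
        center = tm.distance[30, 50:150]
        assert ((center >= 10) & (center <= 11.5)).all()

    def test_isolated_pixel(self):
        m = np.zeros((20, 20), bool)
        m[10, 10] = True
        v = thickness_map(m).distance[10, 10]
        assert 0 <= v <= 1

    def test_full_mode_is_chord_length(self):
        bar = np.zeros((61, 200), bool)
        bar[20:41, :] = True
        tm = thickness_map(bar, mode="full")
        center = tm.distance[30, 50:150]
        assert np.median(center) == pytest.approx(21, abs=2)

    def test_zero_outside_mask_and_fallback_flagged(self):
        disk = disk_mask((100, 100), 50, 50, 30)
        tm = thickness_map(disk)
        assert (tm.distance[~disk] == 0).all()
        assert tm.fallback[50, 50]  # deep interior has undefined normal


class TestExtractSoma:
    def test_recovers_disk_excludes_tubes(self):
        sc = make_neuron_scene(soma_radius_um=8.4, neurite_width_um=1.4, seed=9)
        masks, _ = segment_field(sc.image.channel("tubulin"), PX)
        assert iou(masks.soma_mask, sc.truth["soma_mask"]) >= 0.8
        # tubes excluded: soma must not cover distant neurite pixels
        far_neurite = sc.truth["neurite_mask"] & ~ndi.binary_dilation(
            sc.truth["soma_mask"], iterations=15
        )
        overlap = (masks.soma_mask & far_neurite).sum() / max(far_neurite.sum(), 1)
        assert overlap < 0.02

    def test_all_thin_structures_give_empty_soma(self):
        bar = np.zeros((200, 200), bool)
        bar[90:110, :] = True  # 20 px wide, far below the 100 px threshold
        tm = thickness_map(bar)
        soma = extract_soma(bar, tm, PX)
        assert not soma.any()

    def test_threshold_monotonicity(self):
        sc = make_neuron_scene(seed=4)
        masks, tmap = segment_field(sc.image.channel("tubulin"), PX)
        cell = masks.cell_mask
        areas = [
            extract_soma(cell, tmap, PX, min_thickness_px=t).sum()
            for t in (60, 100, 140)
        ]
        assert areas[0] >= areas[1] >= areas[2]


class TestSplitCompartments:
    def test_empty_soma_makes_neurite_equal_cell(self):
        cell = disk_mask((64, 64), 32, 32, 20)
        m = split_compartments(cell, np.zeros_like(cell))
        assert np.array_equal(m.neurite_mask, cell)

    def test_soma_equal_cell_makes_neurite_empty(self):
        cell = disk_mask((64, 64), 32, 32, 20)
        m = split_compartments(cell, cell)
        assert not m.neurite_mask.any()

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_pixel_count_conservation(self, seed):
        rng = np.random.default_rng(seed)
        cell = rng.random((40, 40)) > 0.5
        soma = cell & (rng.random((40, 40)) > 0.5)
        m = split_compartments(cell, soma)
        assert m.cell_mask.sum() == m.soma_mask.sum() + m.neurite_mask.sum()
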