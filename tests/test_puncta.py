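import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage as ndi

from nervequant.puncta import (
    assign_compartment,
    count_nuclei,
    detect_puncta,
    ellipsoid_axes3d,
    manders,
    oblate_prolate,
    roi_summary,
    roundness2d,
)
from nervequant.segmentation import segment_field, split_compartments
from nervequant.synth import _gaussian_spot, make_neuron_scene, make_puncta_volume

from conftest import disk_mask

PX = 0.07


class TestDetectPuncta:
    def test_planted_spot_count_recovered(self):
        rng = np.random.default_rng(1)
        img = np.zeros((300, 300))
        pts = [(y, x) for y in range(30, 300, 60) for x in range(30, 300, 60)][:20]
        for y, x in pts:
            _gaussian_spot(img, y, x, 2.5, 100.0)
        noisy = rng.poisson(img + 5).astype(float)  # SNR ~ 10 over flat background
        labels = detect_puncta(noisy, PX)
        assert labels.max() == 20

    def test_blank_image_zero_labels(self):
        assert detect_puncta(np.zeros((64, 64)), PX).max() == 0

    def test_min_size_filter(self):
        img = np.zeros((64, 64))
        img[30:32, 30:33] = 100.0  # 6-px spot
        assert detect_puncta(img, PX, min_size_px=10).max() == 0
        assert detect_puncta(img, PX, min_size_px=5).max() == 1

    def test_labels_are_consecutive(self):
        img = np.zeros((128, 128))
        for i, (y, x) in enumerate([(20, 20), (60, 60), (100, 100)]):
            _gaussian_spot(img, y, x, 2.5, 100)
        labels = detect_puncta(img, PX)
        assert sorted(np.unique(labels)) == [0, 1, 2, 3]


class TestAssignCompartment:
    def test_truth_puncta_assigned_to_their_compartments(self, neuron_scene):
        masks, _ = segment_field(neuron_scene.image.channel("tubulin"), PX)
        labels = detect_puncta(neuron_scene.image.channel("organelle"), PX)
        df = assign_compartment(labels, masks)
        counts = df["compartment"].value_counts().to_dict()
        truth = neuron_scene.truth["puncta_counts"]
        assert counts.get("soma", 0) == truth["soma"]
        assert counts.get("neurite", 0) == truth["neurite"]

    def test_object_outside_cell_is_none_and_partition(self):
        cell = disk_mask((100, 100), 50, 50, 20)
        soma = disk_mask((100, 100), 50, 50, 10)
        m = split_compartments(cell, soma)
        labels = np.zeros((100, 100), np.int32)
        labels[50:52, 50:52] = 1   # soma
        labels[50:52, 65:67] = 2   # neurite ring
        labels[5:7, 5:7] = 3       # outside
        df = assign_compartment(labels, m)
        assert dict(zip(df.object_id, df.compartment)) == {1: "soma", 2: "neurite", 3: "none"}
        assert len(df) == 3


class TestRoundness:
    def test_disk_is_round(self):
        disk = disk_mask((101, 101), 50, 50, 30)
        assert roundness2d(disk) == pytest.approx(1.0, abs=0.05)

    def test_4to1_ellipse(self):
        yy, xx = np.mgrid[0:101, 0:101]
        ell = ((yy - 50) / 10.0) ** 2 + ((xx - 50) / 40.0) ** 2 <= 1
        assert roundness2d(ell) == pytest.approx(0.25, abs=0.03)

    def test_scale_invariance(self):
        small = disk_mask((61, 61), 30, 30, 12)
        # same shape at 2x scale
        yy, xx = np.mgrid[0:121, 0:121]
        big = (yy - 60) ** 2 + (xx - 60) ** 2 <= 24**2
        assert roundness2d(small) == pytest.approx(roundness2d(big), abs=0.02)

    def test_rotation_invariance(self):
        yy, xx = np.mgrid[0:141, 0:141]
        ell = ((yy - 70) / 15.0) ** 2 + ((xx - 70) / 45.0) ** 2 <= 1
        rot = ndi.rotate(ell.astype(float), 35, reshape=True, order=1) >= 0.5
        assert roundness2d(ell) == pytest.approx(roundness2d(rot), abs=0.03)

    def test_single_pixel_convention(self):
        m = np.zeros((5, 5), bool)
        m[2, 2] = True
        assert roundness2d(m) == 1.0


class TestEllipsoidAxes:
    def test_unit_sphere(self):
        sc = make_puncta_volume(1, (1.0, 1.0, 1.0), pixel_size_um=0.1, z_step_um=0.1,
                                snr=None, seed=0, rotate=False)
        vox = np.argwhere(sc.truth["labels"] == 1)
        axes, degen = ellipsoid_axes3d(vox, (0.1, 0.1, 0.1))
        assert not degen
        assert np.allclose(axes, 1.0, rtol=0.05)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_rotated_prolate_recovered(self, seed):
        sc = make_puncta_volume(1, (1.5, 0.3, 0.3), pixel_size_um=0.05, z_step_um=0.1,
                                snr=None, seed=seed)
        vox = np.argwhere(sc.truth["labels"] == 1)
        axes, _ = ellipsoid_axes3d(vox, (0.1, 0.05, 0.05))
        assert np.allclose(axes, (1.5, 0.3, 0.3), rtol=0.05)

    def test_anisotropic_spacing_consistency(self):
        a1, _ = ellipsoid_axes3d(
            np.argwhere(make_puncta_volume(1, (1.0, 0.6, 0.6), pixel_size_um=0.07,
                                           z_step_um=0.35, snr=None, seed=3,
                                           rotate=False).truth["labels"] == 1),
            (0.35, 0.07, 0.07),
        )
        a2, _ = ellipsoid_axes3d(
            np.argwhere(make_puncta_volume(1, (1.0, 0.6, 0.6), pixel_size_um=0.1,
                                           z_step_um=0.2, snr=None, seed=3,
                                           rotate=False).truth["labels"] == 1),
            (0.2, 0.1, 0.1),
        )
        assert np.allclose(a1, a2, rtol=0.10)

    def test_coplanar_component_flagged(self):
        vox = np.argwhere(np.ones((1, 5, 5), bool))
        axes, degen = ellipsoid_axes3d(vox, (0.3, 0.1, 0.1))
        assert degen
        assert axes[2] == pytest.approx(0.15)


class TestOblateProlate:
    @pytest.mark.parametrize(
        "abc,expected",
        [
            ((1, 1, 1), (0.0, 0.0)),
            ((10, 1, 1), (0.0, 9 / 11)),   # needle: oblate 0, prolate 0.818
            ((10, 10, 1), (9 / 11, 0.0)),  # disk: oblate 0.818, prolate 0
        ],
    )
    def test_closed_forms(self, abc, expected):
        ob, pr = oblate_prolate(*abc)
        assert (ob, pr) == pytest.approx(expected)

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            oblate_prolate(1.0, 2.0, 0.5)

    @given(st.floats(0.1, 10), st.floats(0.1, 10), st.floats(0.1, 10))
    @settings(max_examples=50, deadline=None)
    def test_bounds(self, x, y, z):
        a, b, c = sorted((x, y, z), reverse=True)
        ob, pr = oblate_prolate(a, b, c)
        assert 0 <= ob < 1 and 0 <= pr < 1


class TestManders:
    def test_identical_channels_and_masks(self):
        img = np.random.default_rng(0).uniform(1, 2, (32, 32))
        m = img > 1.5
        assert manders(img, img, m, m) == pytest.approx((1.0, 1.0))

    def test_disjoint_masks(self):
        a = np.zeros((32, 32), bool)
        b = np.zeros((32, 32), bool)
        a[:10], b[20:] = True, True
        ch = np.ones((32, 32))
        assert manders(ch, ch, a, b) == pytest.approx((0.0, 0.0))

    def test_partial_overlap_fraction(self):
        maskA = np.zeros((20, 20), bool)
        maskA[:5, :20] = True  # 100 px
        maskB = np.zeros((20, 20), bool)
        maskB[:5, :8] = True   # covers 40 of them
        chA = np.where(maskA, 3.0, 0.0)
        m1, _ = manders(chA, chA, maskA, maskB)
        assert m1 == pytest.approx(0.4)

    def test_empty_mask_reported_missing(self):
        ch = np.ones((8, 8))
        m1, m2 = manders(ch, ch, np.zeros((8, 8), bool), np.ones((8, 8), bool))
        assert np.isnan(m1) and m2 == pytest.approx(0.0)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(3)
        chA, chB = rng.uniform(0, 1, (2, 16, 16))
        mA, mB = chA > 0.4, chB > 0.6
        m1, m2 = manders(chA, chB, mA, mB)
        s2, s1 = manders(chB, chA, mB, mA)
        assert (m1, m2) == pytest.approx((s1, s2))


class TestRoiSummary:
    def test_total_area_arithmetic(self):
        labels = np.zeros((100, 100), np.int32)
        labels[10:15, 10:15] = 1
        labels[30:35, 30:35] = 2
        labels[50:55, 50:55] = 3  # 3 objects x 25 px
        roi = np.ones((100, 100), bool)
        s = roi_summary(labels, roi, PX)
        assert s["count"] == 3
        assert s["total_area_um2"] == pytest.approx(75 * 0.0049)

    def test_half_coverage_fraction(self):
        labels = np.zeros((10, 10), np.int32)
        labels[:5] = 1
        s = roi_summary(labels, np.ones((10, 10), bool), PX)
        assert s["area_fraction_pct"] == pytest.approx(50.0)

    def test_empty_labels_and_empty_roi(self):
        s = roi_summary(np.zeros((10, 10), np.int32), np.ones((10, 10), bool), PX)
        assert s["count"] == 0 and s["area_fraction_pct"] == 0
        with pytest.raises(ValueError):
            roi_summary(np.zeros((10, 10), np.int32), np.zeros((10, 10), bool), PX)


class TestCountNuclei:
    def test_separated_nuclei(self):
        img = np.zeros((512, 512))
        pts = [(60, 60), (60, 200), (60, 380), (200, 100), (200, 300), (380, 80), (380, 420)]
        for y, x in pts:
            _gaussian_spot(img, y, x, 18, 100)
        assert count_nuclei(img, 0.2) == 7

    def test_touching_nuclei_split_by_watershed(self):
        img = np.zeros((256, 256))
        _gaussian_spot(img, 128, 100, 16, 100)
        _gaussian_spot(img, 128, 150, 16, 100)
        assert count_nuclei(img, 0.2) == 2

    def test_blank_field(self):
        assert count_nuclei(np.zeros((64, 64)), 0.2) == 0
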