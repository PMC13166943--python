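import numpy as np
import pytest

from mifquant import (
    ChannelStack,
    SegmentationParams,
    build_tissue_mask,
    preset_spec,
    segment_field,
    segment_membrane,
    segment_nuclei,
)
from mifquant.segmentation import SegmentationError
from mifquant.synthetic import generate_scene
from mifquant.thresholding import PositivityThreshold


def _stack(nuclear=None, membrane=None, px=1.0):
    channels = {}
    if nuclear is not None:
        channels["nuclear_stain"] = nuclear
    if membrane is not None:
        channels["membrane_marker"] = membrane
    return ChannelStack("t", channels, pixel_size_um=px)


def _disks(shape, centers, radius, value=200.0):
    img = np.zeros(shape)
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    for r0, c0 in centers:
        img[(rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2] = value
    return img


FIXED = SegmentationParams(
    nuclear_threshold_method="fixed", nuclear_fixed_threshold=100.0,
    membrane_threshold_method="fixed", membrane_fixed_threshold=100.0,
)


class TestNuclei:
    def test_five_disjoint_disks(self):
        centers = [(20, 20), (20, 60), (60, 20), (60, 60), (100, 100)]
        img = _disks((128, 128), centers, radius=6)
        mask, count = segment_nuclei(_stack(nuclear=img), FIXED)
        assert count == 5
        assert mask.sum() == (img > 100).sum()

    def test_all_zero_image_gives_empty_mask(self):
        mask, count = segment_nuclei(_stack(nuclear=np.zeros((32, 32))), FIXED)
        assert count == 0 and not mask.any()

    def test_otsu_on_constant_image_is_degenerate(self):
        with pytest.raises(SegmentationError, match="degenerate"):
            segment_nuclei(_stack(nuclear=np.full((32, 32), 7.0)), SegmentationParams())

    def test_missing_nuclear_channel(self):
        with pytest.raises(Exception, match="nuclear_stain"):
            segment_nuclei(_stack(membrane=np.zeros((8, 8))), FIXED)

    @pytest.mark.parametrize("connectivity,expected", [(8, 1), (4, 2)])
    def test_diagonal_touch_connectivity(self, connectivity, expected):
        # two 3x3 squares sharing exactly one diagonal pixel pair
        img = np.zeros((16, 16))
        img[2:5, 2:5] = 200.0
        img[5:8, 5:8] = 200.0
        params = SegmentationParams(
            nuclear_threshold_method="fixed", nuclear_fixed_threshold=100.0,
            min_nucleus_area_um2=4.0, connectivity=connectivity,
        )
        _, count = segment_nuclei(_stack(nuclear=img), params)
        assert count == expected

    def test_min_area_rejects_debris(self):
        img = _disks((64, 64), [(20, 20)], radius=6)
        img[50, 50] = 200.0  # 1-px speck
        params = SegmentationParams(
            nuclear_threshold_method="fixed", nuclear_fixed_threshold=100.0,
            min_nucleus_area_um2=10.0,
        )
        mask, count = segment_nuclei(_stack(nuclear=img), params)
        assert count == 1 and not mask[50, 50]

    def test_watershed_splits_touching_pair(self):
        img = _disks((64, 64), [(30, 24)], radius=7) + _disks((64, 64), [(30, 36)], radius=7)
        img = np.clip(img, 0, 200)
        params = SegmentationParams(
            nuclear_threshold_method="fixed", nuclear_fixed_threshold=100.0,
            split_touching_nuclei=True,
        )
        _, count = segment_nuclei(_stack(nuclear=img), params)
        assert count == 2

    def test_count_invariant_to_translation_and_rotation(self):
        spec = preset_spec("moderate", seed=5, height=96, width=96, n_cells=4)
        stack, _ = generate_scene(spec)
        # pad so translation cannot wrap a cell across the field border
        img = np.pad(stack.channel("nuclear_stain").astype(float), 8)
        _, n0 = segment_nuclei(_stack(nuclear=img), FIXED)
        _, n_rot = segment_nuclei(_stack(nuclear=np.rot90(img).copy()), FIXED)
        shifted = np.roll(img, (3, -2), axis=(0, 1))
        _, n_shift = segment_nuclei(_stack(nuclear=shifted), FIXED)
        assert n0 == n_rot == n_shift


class TestMembrane:
    def test_annulus_recovered_exactly(self):
        img = np.full((64, 64), 5.0)
        rr, cc = np.ogrid[:64, :64]
        d2 = (rr - 32) ** 2 + (cc - 32) ** 2
        annulus = (d2 <= 20**2) & (d2 > 16**2)
        img[annulus] = 200.0
        mask = segment_membrane(_stack(membrane=img), FIXED)
        np.testing.assert_array_equal(mask, annulus)

    def test_threshold_above_max_empty(self):
        img = np.random.default_rng(1).uniform(0, 50, (32, 32))
        params = SegmentationParams(
            membrane_threshold_method="fixed", membrane_fixed_threshold=60.0
        )
        assert not segment_membrane(_stack(membrane=img), params).any()

    def test_matches_per_pixel_loop(self, mask_rng):
        img = mask_rng.uniform(0, 255, (40, 40))
        mask = segment_membrane(_stack(membrane=img), FIXED)
        brute = sum(img[i, j] > 100.0 for i in range(40) for j in range(40))
        assert mask.sum() == brute

    def test_control_derived_requires_threshold(self):
        params = SegmentationParams(membrane_threshold_method="control_derived")
        with pytest.raises(SegmentationError, match="control_derived"):
            segment_membrane(_stack(membrane=np.ones((8, 8))), params)

    def test_control_derived_uses_cutoff(self):
        params = SegmentationParams(membrane_threshold_method="control_derived")
        thr = PositivityThreshold("membrane_marker", 150.0, "fixed", 150.0)
        img = np.array([[100.0, 200.0]])
        mask = segment_membrane(_stack(membrane=img), params, thr)
        np.testing.assert_array_equal(mask, [[False, True]])

    def test_raising_fixed_threshold_never_enlarges_mask(self, mask_rng):
        img = mask_rng.uniform(0, 255, (64, 64))
        prev = None
        for t in (20.0, 80.0, 160.0, 240.0):
            params = SegmentationParams(
                membrane_threshold_method="fixed", membrane_fixed_threshold=t
            )
            mask = segment_membrane(_stack(membrane=img), params)
            if prev is not None:
                assert not (mask & ~prev).any()  # mask(t2) subset of mask(t1)
            prev = mask


class TestTissue:
    def test_zero_dilation_no_membrane_equals_nuclear(self):
        img = _disks((64, 64), [(32, 32)], radius=8)
        params = SegmentationParams(
            nuclear_threshold_method="fixed", nuclear_fixed_threshold=100.0,
            tissue_dilation_um=0.0,
        )
        nuclear, _ = segment_nuclei(_stack(nuclear=img), params)
        tissue = build_tissue_mask(_stack(nuclear=img), params, nuclear_mask=nuclear)
        np.testing.assert_array_equal(tissue, nuclear)

    def test_dilation_monotone(self):
        img = _disks((64, 64), [(32, 32)], radius=8)
        stack = _stack(nuclear=img)
        areas = []
        for r in (0.0, 2.0, 5.0):
            params = SegmentationParams(
                nuclear_threshold_method="fixed", nuclear_fixed_threshold=100.0,
                tissue_dilation_um=r,
            )
            areas.append(build_tissue_mask(stack, params).sum())
        assert areas[0] < areas[1] < areas[2]

    def test_covers_ground_truth_cells_at_default_radius(self):
        spec = preset_spec("moderate", seed=11)
        stack, truth = generate_scene(spec)
        masks = segment_field(stack, SegmentationParams())
        covered = (truth.cell_mask & masks.tissue).sum() / truth.cell_mask.sum()
        assert covered >= 0.99
        assert not (masks.nuclear & ~masks.tissue).any()  # nuclear subset of tissue
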