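import numpy as np
import pytest

from mifquant import (
    PositivityThreshold,
    ROIQuantRecord,
    SegmentationParams,
    assess_evaluability,
    marker_area_per_cell,
    percent_membrane_area_dual_positive,
    percent_membrane_area_positive,
    percent_nuclear_area_positive,
    phospho_total_ratio,
    preset_spec,
    quantify_roi,
    segment_field,
)
from mifquant.synthetic import generate_scene
from tests.conftest import count_loop


def _rand_masks(rng, shape=(64, 64), k=3, p=0.4):
    return [rng.random(shape) < p for _ in range(k)]


class TestAreaPerCell:
    def test_forced_formula(self):
        pos = np.zeros((40, 40), bool)
        pos.flat[:400] = True
        tissue = np.ones((40, 40), bool)
        assert marker_area_per_cell(pos, tissue, 10, 0.5) == pytest.approx(10.0)

    def test_empty_positive_mask_is_zero(self):
        z = np.zeros((8, 8), bool)
        assert marker_area_per_cell(z, np.ones((8, 8), bool), 5, 1.0) == 0.0

    def test_zero_nuclei_is_missing(self):
        m = np.ones((8, 8), bool)
        assert marker_area_per_cell(m, m, 0, 1.0) is None

    def test_scales_with_pixel_size_squared(self, mask_rng):
        pos, tissue = _rand_masks(mask_rng, k=2)
        v1 = marker_area_per_cell(pos, tissue, 7, 1.0)
        v2 = marker_area_per_cell(pos, tissue, 7, 2.0)
        assert v2 == pytest.approx(4.0 * v1)


class TestPercentMetrics:
    def test_map_forced(self):
        membrane = np.zeros((40, 40), bool)
        membrane.flat[:1000] = True
        pos = np.zeros((40, 40), bool)
        pos.flat[:250] = True
        assert percent_membrane_area_positive(pos, membrane) == pytest.approx(25.0)

    def test_map_superset_is_100(self, mask_rng):
        membrane = mask_rng.random((32, 32)) < 0.3
        assert percent_membrane_area_positive(np.ones((32, 32), bool), membrane) == 100.0

    def test_nap_forced(self):
        nuclear = np.zeros((40, 40), bool)
        nuclear.flat[:500] = True
        pos = np.zeros((40, 40), bool)
        pos.flat[:155] = True
        assert percent_nuclear_area_positive(pos, nuclear) == pytest.approx(31.0)

    def test_positive_outside_nuclei_is_zero(self):
        nuclear = np.zeros((16, 16), bool)
        nuclear[:8] = True
        pos = ~nuclear
        assert percent_nuclear_area_positive(pos, nuclear) == 0.0

    def test_empty_denominators_are_missing_not_zero(self):
        z = np.zeros((8, 8), bool)
        o = np.ones((8, 8), bool)
        assert percent_membrane_area_positive(o, z) is None
        assert percent_nuclear_area_positive(o, z) is None
        assert percent_membrane_area_dual_positive(o, o, z) is None

    def test_dual_identity_and_disjoint(self, mask_rng):
        membrane, pos = _rand_masks(mask_rng, k=2)
        assert percent_membrane_area_dual_positive(pos, pos, membrane) == pytest.approx(
            percent_membrane_area_positive(pos, membrane)
        )
        a = np.zeros((8, 8), bool); a[:4] = True
        assert percent_membrane_area_dual_positive(a, ~a, np.ones((8, 8), bool)) == 0.0

    def test_dual_bounded_by_singles(self, mask_rng):
        for _ in range(20):
            a, b, membrane = _rand_masks(mask_rng)
            if not membrane.any():
                continue
            dual = percent_membrane_area_dual_positive(a, b, membrane)
            assert dual <= min(
                percent_membrane_area_positive(a, membrane),
                percent_membrane_area_positive(b, membrane),
            ) + 1e-12

    def test_matches_nested_loop_oracle(self, mask_rng):
        for _ in range(5):
            a, b, membrane = _rand_masks(mask_rng, shape=(32, 32))
            denom = count_loop(membrane)
            assert percent_membrane_area_positive(a, membrane) == 100.0 * count_loop(a, membrane) / denom
            assert percent_membrane_area_dual_positive(a, b, membrane) == 100.0 * count_loop(a, b, membrane) / denom


class TestRatio:
    def test_examples(self):
        assert phospho_total_ratio(5.0, 10.0) == 0.5
        assert phospho_total_ratio(0.0, 3.0) == 0.0
        assert phospho_total_ratio(1.0, 0.0) is None
        assert phospho_total_ratio(None, 2.0) is None


class TestEvaluability:
    def _recs(self, counts, specimen="s1"):
        return [
            ROIQuantRecord(field_id=f"f{i}", roi_id="full", specimen_id=specimen,
                           nucleus_count=c)
            for i, c in enumerate(counts)
        ]

    def test_summation_over_rois(self):
        recs = self._recs([1200, 1200, 1200])
        verdicts = assess_evaluability(recs, min_cells=3000)
        assert verdicts == {"s1": True}
        assert all(r.evaluable for r in recs)

    def test_boundary_below(self):
        recs = self._recs([2999])
        assert assess_evaluability(recs, min_cells=3000) == {"s1": False}
        assert not recs[0].evaluable and "evaluability" in recs[0].qc_notes

    def test_min_zero_everything_evaluable(self):
        recs = self._recs([0, 5])
        assert all(assess_evaluability(recs, min_cells=0).values())


@pytest.fixture(scope="module")
def scene():
    spec = preset_spec("high", seed=9, height=160, width=160, n_cells=8, noise_sd=0.0)
    stack, truth = generate_scene(spec)
    params = SegmentationParams(
        nuclear_threshold_method="fixed", nuclear_fixed_threshold=1000.0,
        membrane_threshold_method="fixed", membrane_fixed_threshold=1000.0,
    )
    masks = segment_field(stack, params)
    thr = {m: PositivityThreshold(m, 1000.0, "fixed", 1000.0)
           for m in ("total_met", "phospho_met")}
    return stack, truth, masks, thr


class TestQuantifyROI:

    def test_full_field_recovers_truth(self, scene):
        stack, truth, masks, thr = scene
        rec = quantify_roi(stack, masks, thr)
        assert rec.nucleus_count == truth.nucleus_count
        assert rec.total_met_pct_map == pytest.approx(
            100.0 * truth.true_fraction[("total_met", "membrane")], abs=1e-9
        )
        assert rec.phospho_total_ratio == pytest.approx(
            rec.phospho_met_area_per_cell_um2 / rec.total_met_area_per_cell_um2
        )

    def test_roi_restriction(self, scene):
        stack, truth, masks, thr = scene
        rec = quantify_roi(stack, masks, thr, roi=(0, 80, 0, 80), roi_id="q1")
        assert rec.roi_id == "q1"
        assert rec.tissue_area_um2 <= quantify_roi(stack, masks, thr).tissue_area_um2

    def test_percent_metrics_pixel_size_invariant(self):
        # same rasters under two physical calibrations: percentages identical,
        # area-per-cell scales with pixel_size^2
        from mifquant import ChannelStack

        spec = preset_spec("moderate", seed=21, height=96, width=96, n_cells=4, noise_sd=0.0)
        base, _ = generate_scene(spec)
        thr = {m: PositivityThreshold(m, 1000.0, "fixed", 1000.0)
               for m in ("total_met", "phospho_met")}
        recs = {}
        for px in (0.5, 1.0):
            stack = ChannelStack("f", dict(base.channels), pixel_size_um=px)
            params = SegmentationParams(
                nuclear_threshold_method="fixed", nuclear_fixed_threshold=1000.0,
                membrane_threshold_method="fixed", membrane_fixed_threshold=1000.0,
                min_nucleus_area_um2=0.0, tissue_dilation_um=10.0 * px,
            )
            masks = segment_field(stack, params)
            recs[px] = quantify_roi(stack, masks, thr)
        assert recs[0.5].total_met_pct_map == recs[1.0].total_met_pct_map
        assert recs[0.5].phospho_met_pct_nap == recs[1.0].phospho_met_pct_nap
        assert recs[0.5].total_met_area_per_cell_um2 == pytest.approx(
            0.25 * recs[1.0].total_met_area_per_cell_um2
        )

    def test_shrinking_positive_mask_never_increases_metrics(self, scene):
        stack, truth, masks, _ = scene
        prev = None
        for cutoff in (500.0, 1500.0, 2600.0):
            thr = {m: PositivityThreshold(m, cutoff, "fixed", cutoff)
                   for m in ("total_met", "phospho_met")}
            rec = quantify_roi(stack, masks, thr)
            if prev is not None:
                for f in ("total_met_pct_map", "phospho_met_pct_map", "pct_map_dual",
                          "total_met_area_per_cell_um2", "phospho_met_area_per_cell_um2"):
                    assert getattr(rec, f) <= getattr(prev, f) + 1e-12
            prev = rec


def count_exact(truth, marker):
    pos = truth.positive_masks[(marker, "membrane")]
    return pos.sum() / truth.membrane_mask.sum()
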