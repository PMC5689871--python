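"""Intensity-difference test, gamma analysis, and QA reports."""

import numpy as np
import pytest

from fluqa.compare import (
    TestCriteria,
    compare_volumes,
    gamma_analysis_3d,
    intensity_difference_test,
    load_report,
    qa_report,
)
from fluqa.exceptions import GridMismatchError
from helpers_oracles import brute_gamma

SPACING = (0.3, 0.3, 0.3)


def blob(shape=(9, 9, 9), peak=100.0):
    """Smooth peaked reference distribution, max = peak at the center."""
    axes = [np.linspace(-1, 1, n) for n in shape]
    g = np.meshgrid(*axes, indexing="ij")
    r2 = sum(a**2 for a in g)
    return peak * np.exp(-2.0 * r2)


class TestCriteriaValidation:
    def test_defaults_are_clinical(self):
        c = TestCriteria()
        assert (c.diff_pct, c.gamma_pct, c.gamma_dta_mm) == (3.0, 3.0, 3.0)
        assert c.low_cutoff_fraction == 0.10
        assert c.action_level_fraction == 0.05

    @pytest.mark.parametrize("kwargs", [
        {"diff_pct": 0.0}, {"gamma_dta_mm": -1.0}, {"low_cutoff_fraction": 1.0},
    ])
    def test_invalid_criteria_rejected(self, kwargs):
        with pytest.raises(ValueError):
            TestCriteria(**kwargs)


class TestIntensityDifference:
    def test_identical_volumes_all_pass(self):
        ref = blob()
        _, f = intensity_difference_test(ref, ref.copy(), spacing=SPACING)
        assert f == 0.0

    def test_single_offset_voxel_counts_once(self):
        ref = blob()
        ev = ref.copy()
        c = TestCriteria()
        mask = ref >= 0.10 * ref.max()
        target = tuple(np.argwhere(mask)[0])
        ev[target] += 0.05 * ref.max()  # 5% of max: a clear failure
        _, f = intensity_difference_test(ref, ev, c, spacing=SPACING)
        assert f == pytest.approx(1.0 / mask.sum())

    def test_uniform_sub_threshold_offset_passes(self):
        ref = blob()
        ev = ref + 0.029 * ref.max()
        _, f = intensity_difference_test(ref, ev, spacing=SPACING)
        assert f == 0.0

    def test_low_voxels_are_excluded_from_denominator(self):
        ref = blob()
        ev = ref.copy()
        cold = ref < 0.10 * ref.max()
        ev[cold] += 0.5 * ref.max()  # huge error, but in excluded voxels
        _, f = intensity_difference_test(ref, ev, spacing=SPACING)
        assert f == 0.0

    def test_diff_map_is_signed_evaluated_minus_reference(self):
        ref = blob()
        ev = ref * 1.01
        diff, _ = intensity_difference_test(ref, ev, spacing=SPACING)
        assert np.all(diff >= 0)
        assert diff.max() == pytest.approx(0.01 * ref.max())

    def test_shape_mismatch_rejected(self):
        with pytest.raises(GridMismatchError):
            intensity_difference_test(blob((5, 5, 5)), blob((6, 6, 6)),
                                      spacing=SPACING)

    def test_all_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            intensity_difference_test(np.zeros((4, 4, 4)), blob((4, 4, 4)),
                                      spacing=SPACING)


class TestGamma:
    def test_identical_volumes_gamma_zero(self):
        ref = blob()
        gmap, f = gamma_analysis_3d(ref, ref.copy(), spacing=SPACING)
        assert f == 0.0
        assert gmap.max() == 0.0

    def test_uniform_offset_at_exactly_criterion_passes(self):
        # on a flat reference there is no gradient for the DTA search to
        # exploit: a uniform 3%-of-max shift pins gamma at exactly 1
        ref = np.full((8, 8, 8), 100.0)
        ev = ref + 0.03 * ref.max()
        gmap, f = gamma_analysis_3d(ref, ev, spacing=SPACING)
        assert np.allclose(gmap, 1.0, atol=1e-9)
        assert f == 0.0  # gamma of exactly 1 counts as a pass

    def test_uniform_offset_just_above_criterion_fails_everywhere(self):
        ref = np.full((8, 8, 8), 100.0)
        ev = ref + 0.033 * ref.max()
        _, f = gamma_analysis_3d(ref, ev, spacing=SPACING)
        assert f == 1.0

    def test_spatial_shift_within_dta_passes(self):
        # a steep ramp (6%-of-max per 3 mm voxel) shifted by one voxel fails
        # the difference test but is fully absorbed by the 3 mm DTA search
        profile = np.concatenate([np.full(4, 40.0), 40.0 + 6.0 * np.arange(1, 7),
                                  np.full(4, 76.0)])
        ref = np.tile(profile[:, None, None], (1, 4, 4))
        ev = np.empty_like(ref)
        ev[1:] = ref[:-1]
        ev[0] = ref[0]
        _, fi = intensity_difference_test(ref, ev, spacing=SPACING,
                                          criteria=TestCriteria(diff_pct=3.0))
        _, fg = gamma_analysis_3d(ref, ev, spacing=SPACING)
        assert fi > 0.0
        assert fg == 0.0

    def test_matches_exhaustive_oracle_on_random_grids(self, rng):
        c = TestCriteria()
        for shape in [(7, 7, 7), (10, 8, 6)]:
            ref = blob(shape)
            ev = ref * (1 + rng.normal(0, 0.02, shape))
            gmap, f = gamma_analysis_3d(ref, ev, c, spacing=SPACING)
            omap, ofail, omask = brute_gamma(ref, ev, SPACING)
            fails = omask & (gmap > 1.0 + 1e-9)
            assert np.array_equal(fails, ofail)
            assert np.allclose(gmap[omask], omap[omask], atol=1e-9)

    def test_gamma_never_exceeds_difference_ratio(self, rng):
        # at zero offset gamma equals the difference ratio, so F_g <= F_I
        ref = blob()
        for _ in range(5):
            ev = ref * (1 + rng.normal(0, 0.03, ref.shape))
            _, fi = intensity_difference_test(ref, ev, spacing=SPACING)
            _, fg = gamma_analysis_3d(ref, ev, spacing=SPACING)
            assert fg <= fi


class TestReports:
    def test_matched_delivery_passes(self, demo_plan_volume, demo_log_volume, tmp_path):
        path = tmp_path / "report.json"
        report = qa_report(demo_plan_volume, demo_log_volume, path=path)
        assert report["verdict"] == "pass"
        assert report["f_intensity"] == 0.0 and report["f_gamma"] == 0.0
        assert load_report(path) == report

    def test_interrupted_delivery_flags_investigation(self, demo_beams, demo_log,
                                                      demo_grid, demo_plan_volume):
        from fluqa.fluence import fluence_from_log
        from fluqa.synthetic import interrupted_delivery

        partial = interrupted_delivery(demo_log, delivered_fraction=0.9)
        v = fluence_from_log(partial, demo_grid)
        report = qa_report(demo_plan_volume, v)
        assert report["f_gamma"] > 0.05
        assert report["verdict"] == "investigate"

    def test_summary_carries_error_statistics(self, demo_plan_volume, demo_log_volume):
        res = compare_volumes(demo_plan_volume, demo_log_volume)
        assert res.max_abs_error_mu >= res.mean_abs_error_mu > 0.0
        assert res.evaluated_voxel_count > 0
        assert 0.0 <= res.f_gamma <= res.f_intensity <= 1.0

    def test_slice_images_written(self, demo_plan_volume, demo_log_volume, tmp_path):
        path = tmp_path / "r.json"
        qa_report(demo_plan_volume, demo_log_volume, path=path, slice_images=True)
        assert path.with_suffix(".png").exists()
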