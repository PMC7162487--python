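"""Generator tests: phantom geometry, forward-model truth, pressure traces."""

import numpy as np
import pytest

from edemaquant import (
    AcquisitionParams,
    GroupEffect,
    SyntheticStudyConfig,
    default_groups,
    generate_phantom,
    simulate_map_trace,
    simulate_study,
    simulate_subject_series,
)
from edemaquant.synthetic import draw_slope


class TestPhantom:
    def test_roi_confined_to_contiguous_slice_block(self, small_params):
        ph = generate_phantom(small_params, seed=1, n_roi_slices=3)
        start, stop = ph.roi_slices
        assert stop - start == 3
        per_slice = ph.roi_mask.reshape(ph.roi_mask.shape[0], -1).any(axis=1)
        assert per_slice[start:stop].all()
        assert not per_slice[:start].any() and not per_slice[stop:].any()

    def test_deterministic_in_seed(self, small_params):
        a = generate_phantom(small_params, seed=1, n_roi_slices=3)
        b = generate_phantom(small_params, seed=1, n_roi_slices=3)
        assert np.array_equal(a.pd_map, b.pd_map)
        assert np.array_equal(a.t2_map, b.t2_map)
        assert np.array_equal(a.roi_mask, b.roi_mask)
        c = generate_phantom(small_params, seed=2, n_roi_slices=3)
        assert not np.array_equal(a.pd_map, c.pd_map)

    def test_t2_in_physiological_band_on_roi(self, small_phantom):
        t2_roi = small_phantom.t2_map[small_phantom.roi_mask]
        assert np.all(t2_roi >= 20.0) and np.all(t2_roi <= 60.0)

    def test_masks_and_positivity(self, small_phantom):
        assert np.all(small_phantom.pd_map >= 0)
        assert not np.any(small_phantom.roi_mask & ~small_phantom.tissue_mask)
        # bone exclusion leaves a hole inside each thigh ellipse
        mid = small_phantom.tissue_mask[small_phantom.tissue_mask.shape[0] // 2]
        assert mid.sum() < np.prod(mid.shape)

    def test_rejects_tiny_matrix(self):
        params = AcquisitionParams(matrix_rows=16, matrix_cols=16, n_slices=3)
        with pytest.raises(ValueError):
            generate_phantom(
                AcquisitionParams(matrix_rows=16, matrix_cols=16, n_slices=3),
                seed=0, n_roi_slices=5,
            )
        # 16x16 itself is the minimum and must work
        generate_phantom(params, seed=0, n_roi_slices=3)


class TestSubjectSeries:
    def test_static_noiseless_series_is_constant(self, small_phantom, small_params,
                                                 noiseless_config):
        eff = GroupEffect("null", 0.0, 0.0, 0.0, 0.0)
        ser = simulate_subject_series(
            small_phantom, eff, noiseless_config, 5, small_params, slope=0.0
        )
        ref = ser.volumes[0].intensities
        for vol in ser.volumes[1:]:
            assert np.array_equal(vol.intensities, ref)

    def test_true_delta_pd_is_linear(self, small_phantom, small_params,
                                     noiseless_config):
        ser = simulate_subject_series(
            small_phantom, default_groups()[1], noiseless_config, 5, small_params,
            slope=0.004,
        )
        assert ser.true_delta_pd[-1] == pytest.approx(0.22, abs=1e-15)
        assert ser.true_delta_pd[0] == 0.0

    def test_zero_sigma_gaussian_equals_noise_free(self, small_phantom, small_params):
        base = dict(groups=default_groups(), n_per_group=2, seed=3)
        cfg_g = SyntheticStudyConfig(noise_model="gaussian", noise_sigma=0.0, **base)
        cfg_n = SyntheticStudyConfig(noise_model="none", noise_sigma=0.0, **base)
        s_g = simulate_subject_series(small_phantom, default_groups()[0], cfg_g, 7,
                                      small_params, slope=0.001)
        s_n = simulate_subject_series(small_phantom, default_groups()[0], cfg_n, 7,
                                      small_params, slope=0.001)
        for vg, vn in zip(s_g.volumes, s_n.volumes):
            assert np.array_equal(vg.intensities, vn.intensities)

    def test_ground_truth_consistency_noiseless(self, small_phantom, small_params,
                                                noiseless_config):
        """ROI-mean amplitude ratio to baseline minus 1 equals a*t+b."""
        ser = simulate_subject_series(
            small_phantom, default_groups()[1], noiseless_config, 9, small_params
        )
        roi = small_phantom.roi_mask
        base = ser.volumes[0].intensities[roi][:, 0].mean()
        for vol, dpd in zip(ser.volumes, ser.true_delta_pd):
            ratio = vol.intensities[roi][:, 0].mean() / base - 1.0
            assert ratio == pytest.approx(
                ser.slope * vol.time_min if vol.time_min > 0 else 0.0, abs=1e-12
            )
            assert ratio == pytest.approx(dpd, abs=1e-12)

    def test_background_contains_noise_only(self, small_phantom, small_params):
        cfg = SyntheticStudyConfig(n_per_group=2, noise_model="none", seed=1)
        ser = simulate_subject_series(small_phantom, default_groups()[0], cfg, 3,
                                      small_params)
        bg = ~small_phantom.tissue_mask
        assert np.all(ser.volumes[0].intensities[bg] == 0.0)

    def test_slope_sampling_calibration(self):
        """Empirical mean/SD of 5000 drawn slopes match the arm parameters."""
        eff = default_groups()[1]  # 0.0047 +/- 0.0008
        rng = np.random.default_rng(123)
        draws = np.array([draw_slope(eff, rng) for _ in range(5000)])
        se_mean = eff.dle_sd / np.sqrt(5000)
        assert abs(draws.mean() - eff.dle_mean) < 3 * se_mean
        se_sd = eff.dle_sd / np.sqrt(2 * (5000 - 1))
        assert abs(draws.std(ddof=1) - eff.dle_sd) < 3 * se_sd

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            SyntheticStudyConfig(noise_sigma=-1.0)


class TestMapTrace:
    def test_zero_effect_gives_zero_reduction(self):
        eff = GroupEffect("null", 0.0, 0.0, 0.0, 0.0)
        trace = simulate_map_trace(eff, subject_seed=0)
        assert trace.reduction == 0.0

    def test_baseline_above_inclusion_threshold(self):
        trace = simulate_map_trace(default_groups()[2], subject_seed=4)
        assert trace.baseline_mean > 150.0

    def test_deterministic(self):
        a = simulate_map_trace(default_groups()[1], subject_seed=8)
        b = simulate_map_trace(default_groups()[1], subject_seed=8)
        assert np.array_equal(a.pressure_mmhg, b.pressure_mmhg)
        assert a.reduction == b.reduction

    def test_solvent_reduction_calibration(self):
        """Sample mean over many animals matches the solvent arm effect."""
        eff = default_groups()[0]  # 2.65 +/- 6.56 mmHg
        reductions = [
            simulate_map_trace(eff, subject_seed=s).reduction for s in range(10_000)
        ]
        se = eff.map_drop_sd / np.sqrt(len(reductions))
        assert abs(np.mean(reductions) - eff.map_drop_mean) < 3 * se

    def test_short_duration_rejected(self):
        with pytest.raises(ValueError):
            simulate_map_trace(default_groups()[0], duration_min=30.0)


class TestStudy:
    def test_study_determinism(self, small_params):
        cfg = SyntheticStudyConfig(n_per_group=2, seed=5)
        s1 = simulate_study(cfg, small_params, n_roi_slices=3)
        s2 = simulate_study(cfg, small_params, n_roi_slices=3)
        spec1, spec2 = s1.subjects[3], s2.subjects[3]
        ser1, tr1, _ = s1.simulate_subject(spec1)
        ser2, tr2, _ = s2.simulate_subject(spec2)
        assert ser1.slope == ser2.slope
        for v1, v2 in zip(ser1.volumes, ser2.volumes):
            assert np.array_equal(v1.intensities, v2.intensities)
        assert np.array_equal(tr1.pressure_mmhg, tr2.pressure_mmhg)

    def test_cohort_layout(self, small_params):
        cfg = SyntheticStudyConfig(n_per_group=4, seed=0)
        study = simulate_study(cfg, small_params, n_roi_slices=3)
        assert len(study.subjects) == 12
        labels = {cfg.groups[s.group_index].label for s in study.subjects}
        assert labels == {"solvent", "L-CCB", "T&L-CCB"}

    def test_single_subject_cohort_rejected(self):
        with pytest.raises(ValueError):
            SyntheticStudyConfig(n_per_group=1)
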