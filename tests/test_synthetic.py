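import numpy as np
import pytest

from epiwound import (
    ClosureModelParams, SheetParams, SpotFieldParams,
    analyze_profile, correct_baseline, detect_peaks, extract_profile,
    make_closure_series, make_epithelial_sheet_image, make_profile,
    make_uptake_images, percent_of_original, radial_line_rois,
)


class TestDeterminism:
    """Identical (params, seed) must give bit-identical outputs."""

    def test_sheet(self):
        p = SheetParams(wound_area_mm2=0.02, pixel_size_um=2.0, seed=7)
        a, _ = make_epithelial_sheet_image(p)
        b, _ = make_epithelial_sheet_image(p)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_profile(self):
        a, _ = make_profile(3, amplitudes=[5, 4, 3], noise_sd=2, seed=9)
        b, _ = make_profile(3, amplitudes=[5, 4, 3], noise_sd=2, seed=9)
        np.testing.assert_array_equal(a.intensities, b.intensities)

    def test_uptake(self):
        p = SpotFieldParams(n_particles=5, n_nuclei=4, seed=3,
                            field_size_um=120, pixel_size_um=1.0)
        fa, ta = make_uptake_images(p, eu_positive_fraction=0.5)
        fb, tb = make_uptake_images(p, eu_positive_fraction=0.5)
        np.testing.assert_array_equal(fa.particles.pixels, fb.particles.pixels)
        np.testing.assert_array_equal(fa.eu.pixels, fb.eu.pixels)
        np.testing.assert_array_equal(ta.eu_positive_flags, tb.eu_positive_flags)

    def test_closure(self):
        p = ClosureModelParams(noise_cv=0.1, seed=11, n_frames=30)
        a, _ = make_closure_series(p)
        b, _ = make_closure_series(p)
        np.testing.assert_array_equal(a.areas_mm2, b.areas_mm2)


class TestSheet:
    def test_all_zero_amplitudes_blank_image(self):
        p = SheetParams(edge_amplitudes=(0, 0, 0, 0, 0), noise_sd=0,
                        wound_area_mm2=0.02, pixel_size_um=2.0, seed=1)
        img, _ = make_epithelial_sheet_image(p)
        assert img.pixels.max() == 0.0

    def test_wound_too_large_names_areas(self):
        p = SheetParams(wound_area_mm2=0.125, field_size_um=400, seed=0)
        with pytest.raises(ValueError, match=r"0\.125.*does not fit"):
            make_epithelial_sheet_image(p)

    def test_end_to_end_ratio_recovery(self):
        """Radial-line analysis recovers the generated rank ratios."""
        p = SheetParams(wound_area_mm2=0.02, pixel_size_um=1.0, seed=3,
                        edge_amplitudes=(200, 100, 80, 60, 10), noise_sd=2)
        img, truth = make_epithelial_sheet_image(p)
        rois = radial_line_rois(img, truth, 8, seed=3)
        ratios = np.array([
            [np.nan if r is None else r
             for r in analyze_profile(extract_profile(img, roi)).ratios]
            for roi in rois
        ])
        mean = np.nanmean(ratios, axis=0)
        np.testing.assert_allclose(mean, [1.0, 0.5, 0.4, 0.3], atol=0.05)


class TestProfileGenerator:
    def test_no_peaks_flat_baseline(self):
        prof, _ = make_profile(0, baseline=7.0, noise_sd=0)
        assert np.all(prof.intensities == 7.0)

    def test_truth_centers_on_cell_grid(self):
        _, truth = make_profile(4, amplitudes=[4, 3, 2, 1], first_center_um=30)
        np.testing.assert_allclose(truth.peak_centers_um, [30, 80, 130, 180])

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            make_profile(2, amplitudes=[5, -1])

    @pytest.mark.parametrize("seed", [3, 21, 34])
    def test_noisy_centers_recovered_within_2um(self, seed):
        from scipy.ndimage import gaussian_filter1d
        from epiwound import IntensityProfile

        prof, truth = make_profile(4, amplitudes=[100, 100, 100, 100],
                                   noise_sd=2, seed=seed, shape="gaussian")
        corr = correct_baseline(prof)
        # the same light pre-smoothing the analysis pipeline applies
        smooth = IntensityProfile(
            corr.positions_um, gaussian_filter1d(corr.intensities, 2.0 / 0.5)
        )
        peaks = detect_peaks(smooth)
        assert len(peaks) == 4
        got = np.array([p.position_um for p in peaks])
        np.testing.assert_allclose(got, truth.peak_centers_um, atol=2.0)

    def test_noise_monotonically_degrades_center_recovery(self):
        """Aggregate center error is non-decreasing in the noise level."""
        errs = []
        for noise in (0.0, 4.0, 12.0):
            tot = 0.0
            for seed in range(20):
                prof, truth = make_profile(4, amplitudes=[200, 100, 80, 60],
                                           noise_sd=noise, seed=seed)
                peaks = detect_peaks(correct_baseline(prof))
                pos = np.array([p.position_um for p in peaks])
                for c in truth.peak_centers_um:
                    tot += np.abs(pos - c).min() if pos.size else 25.0
            errs.append(tot / (20 * 4))
        assert errs[0] <= errs[1] + 1e-12 <= errs[2] + 1e-12


class TestUptakeGenerator:
    def test_zero_particles_channel_is_noise_only(self):
        p = SpotFieldParams(n_particles=0, n_nuclei=3, noise_sd=2,
                            field_size_um=100, pixel_size_um=1.0, seed=4)
        fld, truth = make_uptake_images(p)
        assert truth.particle_coords_um.shape == (0, 2)
        assert fld.particles.pixels.max() < 12  # ~ a few noise SDs

    def test_impossible_separation_raises(self):
        p = SpotFieldParams(n_particles=0, n_nuclei=100, min_separation_um=30,
                            field_size_um=100, pixel_size_um=2.0, seed=0)
        with pytest.raises(ValueError, match="could not place"):
            make_uptake_images(p)

    def test_positive_count_is_rounded_fraction(self):
        p = SpotFieldParams(n_particles=0, n_nuclei=77, seed=5,
                            field_size_um=300)
        _, truth = make_uptake_images(p, eu_positive_fraction=70 / 77)
        assert int(truth.eu_positive_flags.sum()) == 70


class TestClosureGenerator:
    def test_zero_rate_constant_series(self):
        p = ClosureModelParams(rate_constant_per_min=0.0, noise_cv=0,
                               n_frames=20)
        ser, _ = make_closure_series(p)
        np.testing.assert_allclose(ser.areas_mm2, p.initial_area_mm2)

    def test_half_life_closed_form(self):
        # k = ln2 / 10 min and a frame exactly at t = 10 min
        p = ClosureModelParams(rate_constant_per_min=np.log(2) / 10,
                               frame_interval_s=60, n_frames=11, noise_cv=0)
        ser, _ = make_closure_series(p)
        assert ser.areas_mm2[10] == pytest.approx(p.initial_area_mm2 / 2,
                                                  rel=1e-12)

    def test_front_model_reaches_zero(self):
        p = ClosureModelParams(initial_area_mm2=0.01, speed_um_per_min=20,
                               frame_interval_s=60, n_frames=400, noise_cv=0)
        ser, _ = make_closure_series(p)
        assert ser.areas_mm2[0] == pytest.approx(0.01)
        assert ser.areas_mm2[-1] == 0.0
        assert (np.diff(ser.areas_mm2) <= 1e-15).all()
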