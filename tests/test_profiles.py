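import numpy as np
import pytest

from oracles import brute_force_opening, brute_force_peaks

from epiwound import (
    CalibratedImage, IntensityProfile, LineROI, Peak, PeakDetectionParams,
    LineRecord, aggregate_ratios, analyze_profile, assign_cell_edges,
    correct_baseline, detect_peaks, extract_profile, make_profile,
)
from epiwound.profiles import CellEdgeSeries


def _profile(y, step=1.0):
    y = np.asarray(y, dtype=float)
    return IntensityProfile(np.arange(len(y)) * step, y)


class TestExtractProfile:
    def test_constant_image_constant_profile(self):
        img = CalibratedImage(np.full((20, 30), 7.0), 0.5)
        prof = extract_profile(img, LineROI((2, 1), (2, 25)))
        assert np.all(prof.intensities == 7.0)
        assert len(prof) == 25  # floor(24/1)+1
        assert prof.positions_um[-1] == pytest.approx(12.0)  # 24 px * 0.5 µm

    def test_bright_column_hand_computed_bilinear(self):
        # single bright column at col 3; a horizontal line at a half-pixel
        # row must read the average of the two neighbouring rows
        px = np.zeros((5, 7))
        px[2, 3] = 10.0
        img = CalibratedImage(px, 1.0)
        prof = extract_profile(img, LineROI((2.0, 0.0), (2.0, 6.0)))
        np.testing.assert_allclose(prof.intensities,
                                   [0, 0, 0, 10, 0, 0, 0])
        half = extract_profile(img, LineROI((1.5, 0.0), (1.5, 6.0)))
        np.testing.assert_allclose(half.intensities, [0, 0, 0, 5, 0, 0, 0])
        assert int(np.argmax(prof.intensities)) == 3

    def test_wound_end_swap_reverses_profile(self):
        img = CalibratedImage(np.tile(np.arange(10.0), (4, 1)), 1.0)
        fwd = extract_profile(img, LineROI((1, 0), (1, 9), "start"))
        rev = extract_profile(img, LineROI((1, 0), (1, 9), "end"))
        np.testing.assert_allclose(rev.intensities, fwd.intensities[::-1])

    def test_line_outside_image_rejected(self):
        img = CalibratedImage(np.zeros((5, 5)), 1.0)
        with pytest.raises(ValueError, match="outside image"):
            extract_profile(img, LineROI((1, 1), (1, 10)))


class TestCorrectBaseline:
    def test_constant_profile_goes_to_zero(self):
        out = correct_baseline(_profile(np.full(200, 42.0)), 80)
        assert np.all(out.intensities == 0.0)

    def test_offset_invariance(self):
        rng = np.random.default_rng(1)
        y = np.clip(rng.normal(20, 5, 300), 0, None)
        a = correct_baseline(_profile(y), 80).intensities
        b = correct_baseline(_profile(y + 100), 80).intensities
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_gaussian_on_ramp_amplitude_preserved(self):
        x = np.arange(0, 300, 0.5)
        sig = 30 / 2.355
        y = 100 * np.exp(-0.5 * ((x - 150) / sig) ** 2) + 0.1 * x + 10
        out = correct_baseline(IntensityProfile(x, y), 80)
        assert out.intensities.max() == pytest.approx(100, rel=0.05)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_opening(self, seed):
        rng = np.random.default_rng(seed)
        y = np.clip(rng.normal(30, 15, 400), 0, None)
        prof = _profile(y, step=0.5)
        got = correct_baseline(prof, 80).intensities
        expected = np.clip(y - brute_force_opening(y, 161), 0, None)
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_window_shorter_than_3_samples_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            correct_baseline(_profile(np.zeros(50), step=50.0), 80)


class TestDetectPeaks:
    def test_monotone_ramp_has_no_peaks(self):
        assert detect_peaks(_profile(np.arange(100.0))) == []

    def test_width_band_straddling_bumps(self):
        """A 30 µm bump is kept; a 10 µm bump is outside the printed band."""
        x = np.arange(0, 200, 0.5)
        wide = 50 * np.exp(-np.log(2) * ((x - 60) / 15) ** 4)
        narrow = 50 * np.exp(-np.log(2) * ((x - 150) / 5) ** 4)
        prof = IntensityProfile(x, wide + narrow)
        peaks = detect_peaks(prof, PeakDetectionParams(min_prominence=5))
        assert len(peaks) == 1
        assert peaks[0].position_um == pytest.approx(60, abs=1)
        assert 20 <= peaks[0].width_um <= 40

    def test_plateau_resolved_to_center(self):
        y = np.zeros(120)
        y[40:71] = 30.0  # 31-sample plateau, center index 55
        peaks = detect_peaks(_profile(y), PeakDetectionParams(min_prominence=5))
        assert len(peaks) == 1
        assert peaks[0].position_um == 55.0

    def test_too_short_profile_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            detect_peaks(_profile(np.zeros(10)))

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(150, 1200))
        step = float(rng.choice([0.5, 1.0]))
        x = np.arange(n) * step
        y = np.zeros(n)
        for _ in range(int(rng.integers(0, 6))):
            c, w, a = (rng.uniform(0, n * step), rng.uniform(5, 60),
                       rng.uniform(5, 150))
            y += a * np.exp(-0.5 * ((x - c) / (w / 2.355)) ** 2)
        y = np.clip(y + rng.normal(0, rng.uniform(0.5, 6), n), 0, None)
        floor = float(rng.uniform(2, 25))
        got = detect_peaks(IntensityProfile(x, y),
                           PeakDetectionParams(min_prominence=floor))
        expected = brute_force_peaks(y, step, 20.0, 40.0, floor)
        assert [round(p.position_um / step) for p in got] == [i for i, _, _ in expected]
        np.testing.assert_allclose([p.prominence for p in got],
                                   [pr for _, pr, _ in expected], rtol=1e-12)
        np.testing.assert_allclose([p.width_um for p in got],
                                   [w for _, _, w in expected], rtol=1e-9)


class TestScaleInvariance:
    """Ratios must not depend on overall intensity scale or offset."""

    @pytest.mark.parametrize("factor", [0.25, 3.0, 17.0])
    def test_multiplicative_scaling(self, factor):
        prof, _ = make_profile(4, amplitudes=[200, 100, 80, 60],
                               noise_sd=4, seed=5)
        base = analyze_profile(prof)
        scaled = IntensityProfile(prof.positions_um,
                                  prof.intensities * factor)
        got = analyze_profile(
            scaled,
            params=PeakDetectionParams(min_prominence=10 * factor),
        )
        for a, b in zip(base.ratios, got.ratios):
            assert a == pytest.approx(b, abs=1e-9)

    def test_additive_offset_removed_by_baseline(self):
        prof, _ = make_profile(4, amplitudes=[200, 100, 80, 60],
                               noise_sd=4, seed=6)
        base = analyze_profile(prof, params=PeakDetectionParams(min_prominence=10))
        shifted = IntensityProfile(prof.positions_um, prof.intensities + 500)
        got = analyze_profile(shifted,
                              params=PeakDetectionParams(min_prominence=10))
        for a, b in zip(base.ratios, got.ratios):
            assert a == pytest.approx(b, abs=1e-9)


class TestAssignCellEdges:
    def _peaks(self, amps):
        return [Peak(10.0 + 50 * i, a, 30.0, a) for i, a in enumerate(amps)]

    def test_ratio_arithmetic(self):
        s = assign_cell_edges(self._peaks([200, 100, 80, 60]))
        assert s.ratios == (1.0, 0.5, 0.4, 0.3)

    def test_equal_amplitudes(self):
        s = assign_cell_edges(self._peaks([70, 70, 70, 70]))
        assert s.ratios == (1.0, 1.0, 1.0, 1.0)

    def test_two_peaks_leaves_deep_ranks_missing(self):
        s = assign_cell_edges(self._peaks([200, 100]))
        assert s.ratios == (1.0, 0.5, None, None)
        assert not s.qc_flag

    def test_no_peaks_flagged_not_error(self):
        s = assign_cell_edges([])
        assert s.ratios == (None,) * 4
        assert s.qc_flag

    def test_extra_peaks_dropped_by_position(self):
        s = assign_cell_edges(self._peaks([200, 100, 80, 60, 40, 20]))
        assert s.ratios == (1.0, 0.5, 0.4, 0.3)


class TestAggregateRatios:
    def _series(self, r1):
        return CellEdgeSeries((200.0, 200.0 * r1, None, None),
                              (1.0, r1, None, None))

    def test_line_then_wound_then_animal_means(self):
        recs = (
            [LineRecord("a1", "w1", self._series(r)) for r in (0.5, 0.7)]
            + [LineRecord("a1", "w2", self._series(r)) for r in (0.7, 0.9)]
        )
        with pytest.warns(UserWarning):  # 2 lines/wound is below the 4-8 design
            df = aggregate_ratios(recs)
        # wound means 0.6 and 0.8 -> animal mean 0.7
        assert df.loc[0, "ratio_cell1"] == pytest.approx(0.7)
        assert df.loc[0, "n_wounds"] == 2 and df.loc[0, "n_lines"] == 4

    def test_nine_lines_warns_but_computes(self):
        recs = [LineRecord("a1", "w1", self._series(0.5)) for _ in range(9)]
        with pytest.warns(UserWarning, match="9 lines"):
            df = aggregate_ratios(recs)
        assert df.loc[0, "ratio_cell1"] == pytest.approx(0.5)

    def test_animal_without_usable_lines_excluded(self):
        empty = CellEdgeSeries((None,) * 4, (None,) * 4, qc_flag=True)
        recs = (
            [LineRecord("bad", "w1", empty) for _ in range(4)]
            + [LineRecord("good", "w1", self._series(0.5)) for _ in range(4)]
        )
        df = aggregate_ratios(recs)
        assert list(df["animal"]) == ["good"]
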