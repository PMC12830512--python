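import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_chromatogram
from radiotlc import analyze
from radiotlc.analyze import (
    BaselineStats,
    Region,
    RegionSet,
    analyze_strip,
    baseline_stats,
    fwhm,
    integrate_region,
    rcp_dual_strip,
    read_regions,
    relative_percentages,
    retention_factor,
    snr,
    write_regions,
)
from radiotlc.chromio import parse_record, serialize_record
from radiotlc.errors import (
    IntegrityError,
    InsufficientBaselineError,
    InvalidMarksError,
    RegionBoundsError,
    UndefinedFWHMError,
    UndefinedPercentageError,
)
from radiotlc.simulate import ScanConfig, make_scenario, simulate_scan

BG = Region("baseline", 0.0, 10.0, "background")


class TestBaselineStats:
    def test_constant_counts(self):
        chrom = make_chromatogram([7] * 40)
        stats = baseline_stats(chrom, BG)
        assert stats.mean_counts_per_channel == 7.0
        assert stats.noise_pp_counts == 0.0

    def test_alternating_counts(self):
        chrom = make_chromatogram([4, 6] * 20)
        stats = baseline_stats(chrom, BG)
        assert stats.mean_counts_per_channel == 5.0
        assert stats.noise_pp_counts == 2.0

    def test_seeded_poisson_baseline(self):
        rng = np.random.default_rng(7)
        draws = rng.poisson(25, size=40)
        chrom = make_chromatogram(draws)
        stats = baseline_stats(chrom, Region("bg", 0.0, 20.0, "background"))
        assert stats.mean_counts_per_channel == pytest.approx(draws.mean())
        assert stats.noise_pp_counts == draws.max() - draws.min()

    def test_too_few_channels(self):
        chrom = make_chromatogram([1] * 40)
        with pytest.raises(InsufficientBaselineError):
            baseline_stats(chrom, Region("bg", 0.0, 0.5, "background"))


class TestIntegrateRegion:
    def test_pure_baseline_is_zero(self):
        chrom = make_chromatogram([5] * 40)
        base = BaselineStats(5.0, 0.0)
        assert integrate_region(chrom, Region("a", 10.0, 20.0), base) == 0.0

    def test_additivity_over_disjoint_regions(self):
        rng = np.random.default_rng(1)
        chrom = make_chromatogram(rng.integers(0, 100, size=60))
        base = BaselineStats(3.0, 1.0)
        a = integrate_region(chrom, Region("a", 0.0, 10.0), base)
        b = integrate_region(chrom, Region("b", 10.0, 25.0), base)
        ab = integrate_region(chrom, Region("ab", 0.0, 25.0), base)
        assert ab == pytest.approx(a + b)

    def test_rectangular_pulse(self):
        counts = [5] * 40
        counts[10:18] = [15] * 8  # +10 over 8 channels
        chrom = make_chromatogram(counts)
        base = BaselineStats(5.0, 0.0)
        net = integrate_region(chrom, Region("p", 5.0, 9.0), base)
        assert net == 80.0

    def test_out_of_range_region(self):
        chrom = make_chromatogram([5] * 10)
        with pytest.raises(RegionBoundsError):
            integrate_region(chrom, Region("p", 0.0, 50.0), BaselineStats(5, 0))


class TestRelativePercentages:
    def test_single_region(self):
        assert relative_percentages([123.4]) == pytest.approx([100.0])

    def test_impurity_design_value(self):
        percents = relative_percentages([7.4, 0.4])
        assert percents[0] == pytest.approx(100 * 7.4 / 7.8)
        assert percents[1] == pytest.approx(100 * 0.4 / 7.8)
        assert percents[1] == pytest.approx(5.13, abs=0.005)

    def test_equal_areas(self):
        assert relative_percentages([2.0] * 4) == pytest.approx([25.0] * 4)

    def test_negative_area_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            percents = relative_percentages([10.0, -5.0])
        assert percents == pytest.approx([100.0, 0.0])

    def test_all_nonpositive_raises(self):
        with pytest.raises(UndefinedPercentageError):
            with pytest.warns(UserWarning):
                relative_percentages([-1.0, -2.0])

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=0.01, max_value=1e6, allow_nan=False),
            min_size=1,
            max_size=8,
        )
    )
    def test_percentages_sum_to_100(self, areas):
        assert relative_percentages(areas).sum() == pytest.approx(100.0, abs=1e-9)


class TestRetentionFactor:
    def test_peak_at_origin(self):
        assert retention_factor(10.0, 10.0, 110.0) == 0.0

    def test_peak_at_front(self):
        assert retention_factor(110.0, 10.0, 110.0) == 1.0

    def test_nine_spot_grid(self):
        for k in range(1, 10):
            assert retention_factor(10.0 * k, 0.0, 100.0) == pytest.approx(k / 10)

    def test_invalid_marks(self):
        with pytest.raises(InvalidMarksError):
            retention_factor(50.0, 100.0, 10.0)

    def test_out_of_strip_warns(self):
        with pytest.warns(UserWarning, match="outside"):
            retention_factor(150.0, 0.0, 100.0)

    @settings(max_examples=50, deadline=None)
    @given(
        peak=st.floats(0, 100),
        scale=st.floats(0.1, 10),
        shift=st.floats(-50, 50),
    )
    def test_affine_invariance(self, peak, scale, shift):
        rf = retention_factor(peak, 0.0, 100.0)
        rf2 = retention_factor(peak * scale + shift, shift, 100.0 * scale + shift)
        assert rf2 == pytest.approx(rf, abs=1e-9)


class TestSnr:
    def test_loq_threshold_example(self):
        # H = 5h gives SNR 10, the LOQ acceptance threshold
        assert snr(50.0, 10.0) == 10.0

    def test_zero_height(self):
        assert snr(0.0, 3.0) == 0.0

    def test_half_noise_height(self):
        assert snr(1.5, 3.0) == 1.0

    def test_zero_noise_sentinel(self):
        with pytest.warns(UserWarning, match="infinite"):
            assert snr(5.0, 0.0) == math.inf

    def test_shift_invariance_through_analysis(self):
        # adding a constant to all counts moves height and baseline together
        rng = np.random.default_rng(3)
        counts = rng.poisson(20, size=80)
        counts[40:46] += 500
        regions = RegionSet(
            (
                Region("p", 18.0, 25.0, "peak"),
                Region("bg", 0.0, 15.0, "background"),
            )
        )
        r1 = analyze_strip(make_chromatogram(counts), regions)
        r2 = analyze_strip(make_chromatogram(counts + 1000), regions)
        assert r2.peaks[0].snr == pytest.approx(r1.peaks[0].snr)


class TestFwhm:
    def test_gaussian_sigma_1p486(self, gaussian_chromatogram):
        chrom, center = gaussian_chromatogram(sigma_mm=1.486)
        base = BaselineStats(100.0, 0.0)
        width = fwhm(chrom, Region("p", center - 10, center + 10), base)
        assert width == pytest.approx(3.5, abs=0.25)

    @pytest.mark.parametrize("sigma", [1.0, 1.486, 2.0, 3.0, 4.0, 5.0])
    def test_gaussian_oracle(self, gaussian_chromatogram, sigma):
        chrom, center = gaussian_chromatogram(sigma_mm=sigma)
        base = BaselineStats(100.0, 0.0)
        width = fwhm(chrom, Region("p", center - 8 * sigma, center + 8 * sigma), base)
        assert abs(width - 2.3548 * sigma) <= 0.5  # one channel pitch

    def test_scale_equivariance(self, gaussian_chromatogram):
        base = BaselineStats(100.0, 0.0)
        widths = []
        for sigma in (1.5, 3.0):
            chrom, center = gaussian_chromatogram(sigma_mm=sigma)
            widths.append(
                fwhm(chrom, Region("p", center - 30, center + 30), base)
            )
        assert widths[1] == pytest.approx(2 * widths[0], rel=0.02)

    def test_symmetric_triangle(self):
        # triangle of half-width 10 channels (5 mm) at base -> 5 mm at half height
        up = list(range(0, 1100, 100))
        counts = up + up[-2::-1] + [0] * 20
        chrom = make_chromatogram(counts)
        width = fwhm(chrom, Region("p", 0.0, 15.0), BaselineStats(0.0, 0.0))
        assert width == pytest.approx(5.0, abs=0.5)

    def test_peak_below_baseline(self):
        chrom = make_chromatogram([5] * 40)
        with pytest.raises(UndefinedFWHMError):
            fwhm(chrom, Region("p", 5.0, 15.0), BaselineStats(10.0, 0.0))

    def test_crossing_outside_region(self, gaussian_chromatogram):
        chrom, center = gaussian_chromatogram(sigma_mm=3.0)
        with pytest.raises(UndefinedFWHMError):
            fwhm(chrom, Region("p", center - 1.0, center + 1.0), BaselineStats(100, 0))


class TestRegionSet:
    def test_requires_one_background(self):
        with pytest.raises(RegionBoundsError):
            RegionSet((Region("a", 0, 10, "peak"),))

    def test_rejects_two_backgrounds(self):
        with pytest.raises(RegionBoundsError):
            RegionSet(
                (
                    Region("a", 0, 10, "peak"),
                    Region("b", 20, 30, "background"),
                    Region("c", 40, 50, "background"),
                )
            )

    def test_rejects_overlapping_peaks(self):
        with pytest.raises(RegionBoundsError):
            RegionSet(
                (
                    Region("a", 0, 10, "peak"),
                    Region("b", 5, 15, "peak"),
                    Region("bg", 20, 30, "background"),
                )
            )

    def test_region_csv_round_trip(self, tmp_path):
        rs = RegionSet(
            (
                Region("main", 10.0, 30.0, "peak"),
                Region("impurity", 90.0, 110.0, "peak"),
                Region("baseline", 40.0, 80.0, "background"),
            )
        )
        path = tmp_path / "regions.csv"
        write_regions(rs, path)
        assert read_regions(path) == rs


class TestAnalyzeStrip:
    def _repeatability_regions(self):
        return RegionSet(
            (
                Region("main", 10.0, 30.0, "peak"),
                Region("impurity", 90.0, 110.0, "peak"),
                Region("baseline", 40.0, 80.0, "background"),
            )
        )

    def test_repeatability_impurity_near_design(self):
        model, config = make_scenario("repeatability", seed=11)
        chrom = simulate_scan(model, config)
        report = analyze_strip(chrom, self._repeatability_regions(), main_label="main")
        assert report.impurity_percent == pytest.approx(5.13, abs=0.5)
        assert report.rcp_percent == pytest.approx(94.87, abs=0.5)

    def test_single_spot_rcp_100(self):
        model, config = make_scenario("linearity", seed=2)
        chrom = simulate_scan(model, config)
        regions = RegionSet(
            (
                Region("spot", 50.0, 70.0, "peak"),
                Region("baseline", 15.0, 45.0, "background"),
            )
        )
        report = analyze_strip(chrom, regions)
        assert report.rcp_percent == 100.0

    def test_blank_strip_undefined_percentage(self):
        model, config = make_scenario("background", seed=5)
        chrom = simulate_scan(model, config.replace(background_cps=0.0))
        with pytest.raises(UndefinedPercentageError):
            analyze_strip(chrom, self._repeatability_regions())

    def test_failed_integrity_refused(self):
        model, config = make_scenario("repeatability", seed=1)
        data = serialize_record(simulate_scan(model, config))
        tampered = data.replace(b"# operator=simulator", b"# operator=intruder")
        record = parse_record(tampered)
        assert record.integrity == "failed"
        with pytest.raises(IntegrityError):
            analyze_strip(record, self._repeatability_regions())

    def test_unknown_main_label(self):
        model, config = make_scenario("repeatability", seed=1)
        chrom = simulate_scan(model, config)
        with pytest.raises(RegionBoundsError):
            analyze_strip(chrom, self._repeatability_regions(), main_label="nope")

    def test_end_to_end_recovery(self):
        # spot position within one channel; net area within 4 sqrt(N)
        model, config = make_scenario("linearity", seed=9)
        chrom = simulate_scan(model, config)
        regions = RegionSet(
            (
                Region("spot", 50.0, 70.0, "peak"),
                Region("baseline", 15.0, 45.0, "background"),
            )
        )
        report = analyze_strip(chrom, regions)
        peak = report.peaks[0]
        assert abs(peak.peak_position_mm - 60.0) <= config.step_mm
        expected_area = config.efficiency_cps_per_MBq * 18.5 * chrom.dwell_s
        assert abs(peak.net_area_counts - expected_area) <= 4 * math.sqrt(expected_area)

    def test_percent_sum_invariant(self):
        model, config = make_scenario("repeatability", seed=21)
        chrom = simulate_scan(model, config)
        report = analyze_strip(chrom, self._repeatability_regions())
        assert sum(p.percent for p in report.peaks) == pytest.approx(100.0, abs=1e-9)


class TestDualStrip:
    def _report(self, rcp):
        return analyze.AnalysisReport(
            peaks=(),
            baseline=BaselineStats(1.0, 1.0),
            rcp_percent=rcp,
            main_label="main",
            integrity_status="verified",
        )

    def test_no_impurities(self):
        assert rcp_dual_strip(self._report(100.0), self._report(100.0)) == 100.0

    def test_two_and_three_percent(self):
        assert rcp_dual_strip(self._report(98.0), self._report(97.0)) == pytest.approx(95.0)

    def test_clamped_at_zero_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            assert rcp_dual_strip(self._report(40.0), self._report(40.0)) == 0.0
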