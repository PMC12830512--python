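"""Instrument-qualification suite.

Background, linearity, repeatability, limit of quantification, working
range and positional accuracy, each scored against its printed acceptance
criterion, plus the method-comparison statistics (Pearson correlation,
Shapiro-Wilk normality, Bland-Altman bias and limits of agreement).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from . import analyze, simulate
from .chromio import AcquisitionRecord
from .errors import (
    InvalidParameterError,
    InvalidRangeError,
    PeakMatchingError,
    UndefinedCorrelationError,
    UndefinedCVError,
)
from .simulate import Chromatogram, ScanConfig, decay_activity, make_scenario

__all__ = [
    "LinearityResult",
    "RepeatabilityResult",
    "LoqResult",
    "WorkingRange",
    "MethodComparison",
    "PositionAccuracyResult",
    "BackgroundResult",
    "QualificationRow",
    "QualificationReport",
    "background_assessment",
    "linearity_test",
    "repeatability_test",
    "loq_search",
    "working_range",
    "position_accuracy_test",
    "compare_methods",
    "simulate_method_comparison",
    "run_qualification",
    "default_regions",
]

LINEARITY_R_CRITERION = 0.99
REPEATABILITY_CV_CRITERION = 5.0
LOQ_SNR_CRITERION = 10.0
POSITION_DEVIATION_CRITERION = 10.0
COMPARISON_R_CRITERION = 0.95
WORKING_RANGE_LOQ_FACTOR = 200.0
LOA_Z = 1.96


@dataclass(frozen=True)
class BackgroundResult:
    mean_cps: float
    sd_cps: float
    n_records: int


@dataclass(frozen=True)
class LinearityResult:
    points: tuple[tuple[float, float], ...]  # (calculated MBq, net cps)
    pearson_r: float
    passed: bool

    def __post_init__(self):
        if len(self.points) < 3:
            raise InvalidParameterError("linearity needs >= 3 points")
        if not -1.0 - 1e-12 <= self.pearson_r <= 1.0 + 1e-12:
            raise InvalidParameterError("Pearson r must lie in [-1, 1]")


@dataclass(frozen=True)
class RepeatabilityResult:
    impurity_percents: tuple[float, ...]
    cv_percent: float
    passed: bool

    def __post_init__(self):
        if self.cv_percent < 0:
            raise InvalidParameterError("CV must be >= 0")


@dataclass(frozen=True)
class LoqResult:
    loq_MBq_per_ml: float | None
    snr_at_loq: float | None
    sample_volume_ul: float
    found: bool
    snr_by_concentration: tuple[tuple[float, float], ...] = ()


@dataclass(frozen=True)
class WorkingRange:
    lower_MBq_per_ml: float
    upper_MBq_per_ml: float

    def __post_init__(self):
        if self.lower_MBq_per_ml >= self.upper_MBq_per_ml:
            raise InvalidRangeError(
                f"working-range lower limit ({self.lower_MBq_per_ml}) must be "
                f"below the upper limit ({self.upper_MBq_per_ml})"
            )


@dataclass(frozen=True)
class MethodComparison:
    pairs: tuple[tuple[float, float], ...]  # (test RCP %, reference RCP %)
    pearson_r: float
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    shapiro_w: float
    shapiro_p: float
    pass_r: bool
    normality_ok: bool


@dataclass(frozen=True)
class PositionAccuracyResult:
    expected_rf: tuple[float, ...]
    observed_rf: tuple[float, ...]
    max_deviation_percent: float
    passed: bool

    def __post_init__(self):
        if len(self.expected_rf) != len(self.observed_rf):
            raise InvalidParameterError("Rf lists must have equal length")


@dataclass(frozen=True)
class QualificationRow:
    parameter: str
    criterion: str
    result: str
    passed: bool


@dataclass(frozen=True)
class QualificationReport:
    rows: tuple[QualificationRow, ...]
    seed: int
    background: BackgroundResult
    linearity: LinearityResult
    repeatability: RepeatabilityResult
    loq: LoqResult
    working_range: WorkingRange | None
    position_accuracy: PositionAccuracyResult

    @property
    def all_passed(self) -> bool:
        return all(row.passed for row in self.rows)


def _chromatogram(record) -> Chromatogram:
    return record.chromatogram if isinstance(record, AcquisitionRecord) else record


def background_assessment(records) -> BackgroundResult:
    """Mean and sample SD of the per-record count rate (total counts / total
    time) over replicate blank acquisitions of equal duration."""
    chroms = [_chromatogram(r) for r in records]
    if len(chroms) < 2:
        raise InvalidParameterError("need >= 2 background records")
    durations = [c.total_time_s for c in chroms]
    if not np.allclose(durations, durations[0], rtol=1e-9):
        raise InvalidParameterError("background records differ in duration")
    rates = np.array([c.total_counts / c.total_time_s for c in chroms])
    return BackgroundResult(
        mean_cps=float(rates.mean()),
        sd_cps=float(rates.std(ddof=1)),
        n_records=len(chroms),
    )


def _net_peak_rate_cps(
    chromatogram: Chromatogram,
    peak_region: analyze.Region,
    background_region: analyze.Region,
) -> float:
    baseline = analyze.baseline_stats(chromatogram, background_region)
    net = analyze.integrate_region(chromatogram, peak_region, baseline)
    # whole-spot efficiency is counts per second of dwell, so net counts
    # divided by the per-channel dwell estimates efficiency * activity
    return net / chromatogram.dwell_s


def linearity_test(
    records,
    elapsed_h,
    a0_MBq: float,
    half_life_h: float,
    peak_region: analyze.Region,
    background_region: analyze.Region,
) -> LinearityResult:
    """Pearson correlation of net peak count rate vs calculated activity."""
    chroms = [_chromatogram(r) for r in records]
    if len(chroms) < 3:
        raise InvalidParameterError("linearity needs >= 3 records")
    if len(chroms) != len(elapsed_h):
        raise InvalidParameterError("one elapsed time per record required")
    x = np.array([decay_activity(a0_MBq, t, half_life_h) for t in elapsed_h])
    y = np.array(
        [_net_peak_rate_cps(c, peak_region, background_region) for c in chroms]
    )
    if np.ptp(x) == 0:
        raise UndefinedCorrelationError("all calculated activities identical")
    r = float(stats.pearsonr(x, y).statistic)
    return LinearityResult(
        points=tuple(zip(x.tolist(), y.tolist())),
        pearson_r=r,
        passed=r >= LINEARITY_R_CRITERION,
    )


def repeatability_test(impurity_percents) -> RepeatabilityResult:
    """CV (100 * sample SD / mean) of replicate impurity percentages."""
    values = np.asarray(impurity_percents, dtype=float)
    if len(values) < 2:
        raise InvalidParameterError("repeatability needs >= 2 values")
    mean = values.mean()
    if mean == 0:
        raise UndefinedCVError("mean impurity is zero; CV undefined")
    cv = 100.0 * values.std(ddof=1) / mean
    return RepeatabilityResult(
        impurity_percents=tuple(values.tolist()),
        cv_percent=float(cv),
        passed=bool(cv <= REPEATABILITY_CV_CRITERION),
    )


def _loq_regions() -> tuple[analyze.Region, analyze.Region]:
    peak = analyze.Region("spot", 50.0, 70.0, "peak")
    background = analyze.Region("baseline", 15.0, 45.0, "background")
    return peak, background


def loq_search(
    config: ScanConfig,
    concentrations_MBq_per_ml,
    sample_volume_ul: float = 5.0,
    replicates: int = 3,
    *,
    analytic_noise_pp: float | None = None,
) -> LoqResult:
    """Lowest concentration whose median SNR over replicates is >= 10.

    Each concentration is converted to a spot activity via the sample
    volume, simulated with the single-spot geometry, and analyzed.  With
    ``analytic_noise_pp`` set, sampling is bypassed: SNR is evaluated in
    the deterministic limit 2 * eff * A * w_peak * dwell / noise_pp.
    """
    concentrations = [float(c) for c in concentrations_MBq_per_ml]
    if any(b >= a for a, b in zip(concentrations, concentrations[1:])):
        raise InvalidParameterError("concentrations must be sorted descending")
    if replicates < 1:
        raise InvalidParameterError("replicates must be >= 1")
    peak_region, background_region = _loq_regions()
    seed_seq = np.random.SeedSequence(config.seed)

    medians: list[tuple[float, float]] = []
    for conc in concentrations:
        activity_MBq = conc * sample_volume_ul * 1e-3
        if analytic_noise_pp is not None:
            model, cfg = make_scenario("loq", activity_MBq=activity_MBq)
            cfg = _merge_config(cfg, config)
            n = len(simulate.channel_positions(cfg))
            dwell = cfg.total_time_s / n
            w_peak = simulate.line_spread_weight(
                0.0, cfg.response_sigma_mm, cfg.step_mm
            )
            height = cfg.efficiency_cps_per_MBq * activity_MBq * w_peak * dwell
            median_snr = 2.0 * height / analytic_noise_pp
        else:
            snrs = []
            for child in seed_seq.spawn(replicates):
                model, cfg = make_scenario("loq", activity_MBq=activity_MBq)
                cfg = _merge_config(cfg, config)
                cfg = cfg.replace(seed=int(child.generate_state(1)[0]))
                chrom = simulate.simulate_scan(model, cfg)
                baseline = analyze.baseline_stats(chrom, background_region)
                mask = analyze.region_mask(chrom, peak_region)
                height = float(
                    (chrom.counts[mask] - baseline.mean_counts_per_channel).max()
                )
                if baseline.noise_pp_counts == 0:
                    snrs.append(math.inf if height > 0 else 0.0)
                else:
                    snrs.append(analyze.snr(height, baseline.noise_pp_counts))
            median_snr = float(np.median(snrs))
        medians.append((conc, median_snr))

    qualifying = [(c, s) for c, s in medians if s >= LOQ_SNR_CRITERION]
    if not qualifying:
        return LoqResult(
            loq_MBq_per_ml=None,
            snr_at_loq=None,
            sample_volume_ul=sample_volume_ul,
            found=False,
            snr_by_concentration=tuple(medians),
        )
    loq_conc, loq_snr = min(qualifying, key=lambda cs: cs[0])
    return LoqResult(
        loq_MBq_per_ml=loq_conc,
        snr_at_loq=loq_snr,
        sample_volume_ul=sample_volume_ul,
        found=True,
        snr_by_concentration=tuple(medians),
    )


def _merge_config(scenario_cfg: ScanConfig, user_cfg: ScanConfig) -> ScanConfig:
    """Scenario geometry with the user's instrument parameters."""
    return scenario_cfg.replace(
        efficiency_cps_per_MBq=user_cfg.efficiency_cps_per_MBq,
        background_cps=user_cfg.background_cps,
        response_sigma_mm=user_cfg.response_sigma_mm,
        half_life_h=user_cfg.half_life_h,
        seed=user_cfg.seed,
    )


def working_range(loq_MBq_per_ml: float, max_verified_MBq_per_ml: float) -> WorkingRange:
    """Qualified range: 200 * LOQ up to the highest verified concentration,
    guaranteeing quantification of impurities down to 0.5% of the lower
    limit."""
    if loq_MBq_per_ml <= 0 or max_verified_MBq_per_ml <= 0:
        raise InvalidParameterError("limits must be positive")
    return WorkingRange(
        lower_MBq_per_ml=WORKING_RANGE_LOQ_FACTOR * loq_MBq_per_ml,
        upper_MBq_per_ml=max_verified_MBq_per_ml,
    )


def position_accuracy_test(
    record,
    expected_positions_mm,
    origin_mm: float,
    front_mm: float,
    window_mm: float = 5.0,
) -> PositionAccuracyResult:
    """Observed vs calculated Rf for a row of equally spaced spots.

    Each expected spot is matched to the maximum-count channel inside a
    +-window around its nominal position; a window without a clear peak
    (maximum not above the strip-wide median) is a matching failure.
    """
    chrom = _chromatogram(record)
    expected = sorted(float(p) for p in expected_positions_mm)
    threshold = float(np.median(chrom.counts))
    expected_rf, observed_rf, deviations = [], [], []
    for mu in expected:
        mask = (chrom.positions_mm >= mu - window_mm) & (
            chrom.positions_mm <= mu + window_mm
        )
        if not mask.any():
            raise PeakMatchingError(f"no channels near expected spot at {mu} mm")
        counts = chrom.counts[mask]
        i_max = int(np.argmax(counts))
        if counts[i_max] <= threshold:
            raise PeakMatchingError(
                f"no peak found near expected spot at {mu} mm"
            )
        obs_pos = float(chrom.positions_mm[mask][i_max])
        exp_rf = analyze.retention_factor(mu, origin_mm, front_mm)
        obs_rf = analyze.retention_factor(obs_pos, origin_mm, front_mm)
        expected_rf.append(exp_rf)
        observed_rf.append(obs_rf)
        if exp_rf == 0:
            deviations.append(abs(obs_rf - exp_rf) * 100.0)
        else:
            deviations.append(abs(obs_rf - exp_rf) / exp_rf * 100.0)
    max_dev = float(max(deviations))
    return PositionAccuracyResult(
        expected_rf=tuple(expected_rf),
        observed_rf=tuple(observed_rf),
        max_deviation_percent=max_dev,
        passed=max_dev <= POSITION_DEVIATION_CRITERION,
    )


def compare_methods(pairs) -> MethodComparison:
    """Pearson, Shapiro-Wilk and Bland-Altman statistics for paired RCP
    measurements (test, reference)."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise InvalidParameterError("need >= 3 (test, reference) pairs")
    test, reference = arr[:, 0], arr[:, 1]
    if np.ptp(test) == 0 or np.ptp(reference) == 0:
        raise UndefinedCorrelationError("a series has zero variance")
    diffs = test - reference
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    r = float(stats.pearsonr(test, reference).statistic)
    if np.ptp(diffs) == 0:
        w, p = 1.0, 1.0  # identical differences: trivially "normal"
    else:
        shapiro = stats.shapiro(diffs)
        w, p = float(shapiro.statistic), float(shapiro.pvalue)
    return MethodComparison(
        pairs=tuple(map(tuple, arr.tolist())),
        pearson_r=r,
        bias=bias,
        sd_diff=sd,
        loa_low=bias - LOA_Z * sd,
        loa_high=bias + LOA_Z * sd,
        shapiro_w=w,
        shapiro_p=p,
        pass_r=r >= COMPARISON_R_CRITERION,
        normality_ok=p > 0.05,
    )


def simulate_method_comparison(
    n_pairs: int = 100,
    seed: int = 0,
    impurity_range_percent: tuple[float, float] = (1.0, 6.0),
    reference_efficiency_factor: float = 10.0,
) -> MethodComparison:
    """Paired RCP measurements from two virtual instruments.

    The reference instrument sees ``reference_efficiency_factor`` times the
    count rate of the test instrument (the commercial system records ~10x
    higher rates).  Each pair shares one true strip.
    """
    rng = np.random.default_rng(seed)
    seed_seq = np.random.SeedSequence(seed).spawn(2 * n_pairs)
    regions = default_regions("repeatability")
    pairs = []
    for i in range(n_pairs):
        impurity = float(rng.uniform(*impurity_range_percent))
        model, config = make_scenario("comparison_pair", impurity_percent=impurity)
        rcp = []
        for j, factor in enumerate((1.0, reference_efficiency_factor)):
            cfg = config.replace(
                efficiency_cps_per_MBq=config.efficiency_cps_per_MBq * factor,
                seed=int(seed_seq[2 * i + j].generate_state(1)[0]),
            )
            chrom = simulate.simulate_scan(model, cfg)
            report = analyze.analyze_strip(chrom, regions, main_label="main")
            rcp.append(report.rcp_percent)
        pairs.append((rcp[0], rcp[1]))
    return compare_methods(pairs)


def default_regions(scenario: str) -> analyze.RegionSet:
    """Integration bounds matching each scenario's spot layout."""
    if scenario in ("repeatability", "comparison_pair"):
        return analyze.RegionSet(
            (
                analyze.Region("main", 10.0, 30.0, "peak"),
                analyze.Region("impurity", 90.0, 110.0, "peak"),
                analyze.Region("baseline", 40.0, 80.0, "background"),
            )
        )
    if scenario in ("linearity", "loq"):
        return analyze.RegionSet(
            (
                analyze.Region("spot", 50.0, 70.0, "peak"),
                analyze.Region("baseline", 15.0, 45.0, "background"),
            )
        )
    raise InvalidParameterError(f"no default regions for scenario {scenario!r}")


_LOQ_GRID_MBQ_PER_ML = (50.0, 20.0, 10.0, 5.0, 2.0, 1.0, 0.5)


def run_qualification(
    seed: int = 0, config: ScanConfig | None = None
) -> QualificationReport:
    """Execute every qualification scenario end to end (simulate + analyze)
    and assemble a consolidated report with one row per test."""
    base = config or ScanConfig(scan_range_mm=120.0, total_time_s=120.0)
    seeds = np.random.SeedSequence(seed).spawn(5)

    def sub_seeds(seq, k):
        return [int(c.generate_state(1)[0]) for c in seq.spawn(k)]

    # background: triplicate 5-min blanks
    model, cfg = make_scenario("background")
    cfg = _merge_config(cfg, base)
    blanks = [
        simulate.simulate_scan(model, cfg.replace(seed=s))
        for s in sub_seeds(seeds[0], 3)
    ]
    bg = background_assessment(blanks)

    # linearity: nine scans as an 18.5 MBq spot decays to 2.5 kBq
    model, cfg = make_scenario("linearity")
    cfg = _merge_config(cfg, base)
    offsets = simulate.linearity_offsets_h()
    lin_records = [
        simulate.simulate_scan(model, cfg.replace(seed=s, start_offset_h=float(t)))
        for s, t in zip(sub_seeds(seeds[1], len(offsets)), offsets)
    ]
    lin_regions = default_regions("linearity")
    lin = linearity_test(
        lin_records,
        offsets,
        a0_MBq=18.5,
        half_life_h=cfg.half_life_h,
        peak_region=lin_regions.peaks[0],
        background_region=lin_regions.background,
    )

    # repeatability: six consecutive 2-min scans of the 7.4 + 0.4 MBq strip
    model, cfg = make_scenario("repeatability")
    cfg = _merge_config(cfg, base)
    rep_regions = default_regions("repeatability")
    impurities = []
    for s in sub_seeds(seeds[2], 6):
        chrom = simulate.simulate_scan(model, cfg.replace(seed=s))
        report = analyze.analyze_strip(chrom, rep_regions, main_label="main")
        impurities.append(report.impurity_percent)
    rep = repeatability_test(impurities)

    # LOQ on a descending concentration grid, then the 200x working range
    loq_cfg = base.replace(seed=sub_seeds(seeds[3], 1)[0])
    loq = loq_search(loq_cfg, _LOQ_GRID_MBQ_PER_ML, sample_volume_ul=5.0)
    wrange = None
    if loq.found:
        upper = 18.5 / (5.0 * 1e-3)  # highest linearity activity as MBq/ml
        try:
            wrange = working_range(loq.loq_MBq_per_ml, upper)
        except InvalidRangeError:
            wrange = None

    # positional accuracy: nine spots at 10 mm spacing on a 100 mm strip
    model, cfg = make_scenario("position_accuracy")
    cfg = _merge_config(cfg, base)
    chrom = simulate.simulate_scan(
        model, cfg.replace(seed=sub_seeds(seeds[4], 1)[0])
    )
    pos = position_accuracy_test(
        chrom,
        [s.position_mm for s in model.spots],
        origin_mm=model.origin_mm,
        front_mm=model.front_mm,
    )

    rows = (
        QualificationRow(
            "Background",
            "-",
            f"{bg.mean_cps:.2f} +/- {bg.sd_cps:.2f} cps",
            True,
        ),
        QualificationRow(
            "Linearity",
            f"R > {LINEARITY_R_CRITERION}",
            f"R = {lin.pearson_r:.4f}",
            lin.passed,
        ),
        QualificationRow(
            "Repeatability",
            f"CV < {REPEATABILITY_CV_CRITERION:.0f}%",
            f"CV = {rep.cv_percent:.1f}%",
            rep.passed,
        ),
        QualificationRow(
            "Limit of quantification",
            f"SNR >= {LOQ_SNR_CRITERION:.0f}",
            (
                f"{loq.loq_MBq_per_ml:g} MBq/ml (SNR = {loq.snr_at_loq:.0f})"
                if loq.found
                else "not found"
            ),
            loq.found,
        ),
        QualificationRow(
            "Range",
            "-",
            (
                f"{wrange.upper_MBq_per_ml:g}-{wrange.lower_MBq_per_ml:g} MBq/ml"
                if wrange is not None
                else "undefined"
            ),
            wrange is not None,
        ),
        QualificationRow(
            "Position accuracy",
            f"Deviation from calculated RF <= {POSITION_DEVIATION_CRITERION:.0f}%",
            "Pass" if pos.passed else f"max deviation {pos.max_deviation_percent:.1f}%",
            pos.passed,
        ),
    )
    return QualificationReport(
        rows=rows,
        seed=seed,
        background=bg,
        linearity=lin,
        repeatability=rep,
        loq=loq,
        working_range=wrange,
        position_accuracy=pos,
    )
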