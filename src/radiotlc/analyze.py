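"""Per-region chromatogram metrics and radiochemical purity.

Mirrors the integration spreadsheet: the user supplies region bounds for
peaks and one background region; the module computes background-subtracted
net areas, relative percentages, retention factors, SNR (2H/h convention),
FWHM, and single- or dual-strip RCP.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .chromio import AcquisitionRecord
from .errors import (
    IntegrityError,
    InsufficientBaselineError,
    InvalidMarksError,
    ParseError,
    RegionBoundsError,
    UndefinedFWHMError,
    UndefinedPercentageError,
)
from .simulate import Chromatogram

__all__ = [
    "Region",
    "RegionSet",
    "BaselineStats",
    "PeakResult",
    "AnalysisReport",
    "baseline_stats",
    "integrate_region",
    "relative_percentages",
    "retention_factor",
    "snr",
    "fwhm",
    "analyze_strip",
    "rcp_dual_strip",
    "read_regions",
    "write_regions",
]

REGION_KINDS = ("peak", "background")


@dataclass(frozen=True)
class Region:
    """One labelled integration interval.  Bounds include channels whose
    center lies in ``[start_mm, end_mm)``."""

    label: str
    start_mm: float
    end_mm: float
    kind: str = "peak"

    def __post_init__(self):
        if self.start_mm >= self.end_mm:
            raise RegionBoundsError(
                f"region {self.label!r}: start must precede end"
            )
        if self.kind not in REGION_KINDS:
            raise RegionBoundsError(
                f"region {self.label!r}: kind must be one of {REGION_KINDS}"
            )


@dataclass(frozen=True)
class RegionSet:
    """Validated collection: >= 1 peak region, exactly one background."""

    regions: tuple[Region, ...]

    def __post_init__(self):
        object.__setattr__(self, "regions", tuple(self.regions))
        backgrounds = [r for r in self.regions if r.kind == "background"]
        if len(backgrounds) != 1:
            raise RegionBoundsError(
                f"exactly one background region required, got {len(backgrounds)}"
            )
        peaks = self.peaks
        if not peaks:
            raise RegionBoundsError("at least one peak region required")
        ordered = sorted(peaks, key=lambda r: r.start_mm)
        for a, b in zip(ordered, ordered[1:]):
            if b.start_mm < a.end_mm:
                raise RegionBoundsError(
                    f"peak regions {a.label!r} and {b.label!r} overlap"
                )
        labels = [r.label for r in self.regions]
        if len(set(labels)) != len(labels):
            raise RegionBoundsError("region labels must be unique")

    @property
    def peaks(self) -> tuple[Region, ...]:
        return tuple(r for r in self.regions if r.kind == "peak")

    @property
    def background(self) -> Region:
        return next(r for r in self.regions if r.kind == "background")


@dataclass(frozen=True)
class BaselineStats:
    mean_counts_per_channel: float
    noise_pp_counts: float

    def __post_init__(self):
        if self.noise_pp_counts < 0 or self.mean_counts_per_channel < 0:
            raise InsufficientBaselineError("baseline statistics must be >= 0")


@dataclass(frozen=True)
class PeakResult:
    label: str
    net_area_counts: float
    percent: float
    rf: float
    snr: float
    fwhm_mm: float | None
    peak_position_mm: float
    peak_height_counts: float


@dataclass(frozen=True)
class AnalysisReport:
    peaks: tuple[PeakResult, ...]
    baseline: BaselineStats
    rcp_percent: float
    main_label: str
    integrity_status: str

    def __post_init__(self):
        if not 0 <= self.rcp_percent <= 100:
            raise UndefinedPercentageError("RCP must lie in [0, 100]")

    @property
    def impurity_percent(self) -> float:
        return 100.0 - self.rcp_percent


def region_mask(chromatogram: Chromatogram, region: Region) -> np.ndarray:
    pos = chromatogram.positions_mm
    lo, hi = pos[0] - chromatogram.step_mm / 2, pos[-1] + chromatogram.step_mm / 2
    if region.start_mm < lo - 1e-9 or region.end_mm > hi + 1e-9:
        raise RegionBoundsError(
            f"region {region.label!r} [{region.start_mm}, {region.end_mm}) "
            f"outside scanned range [{lo}, {hi}]"
        )
    return (pos >= region.start_mm) & (pos < region.end_mm)


def baseline_stats(chromatogram: Chromatogram, background_region: Region) -> BaselineStats:
    """Flat mean and peak-to-peak (max - min) noise of the background region."""
    mask = region_mask(chromatogram, background_region)
    counts = chromatogram.counts[mask]
    if len(counts) < 2:
        raise InsufficientBaselineError(
            f"background region {background_region.label!r} has "
            f"{len(counts)} channel(s); need >= 2"
        )
    return BaselineStats(
        mean_counts_per_channel=float(counts.mean()),
        noise_pp_counts=float(counts.max() - counts.min()),
    )


def integrate_region(
    chromatogram: Chromatogram, region: Region, baseline: BaselineStats
) -> float:
    """Net area: sum over region channels of (counts - baseline mean)."""
    mask = region_mask(chromatogram, region)
    counts = chromatogram.counts[mask]
    return float(counts.sum() - len(counts) * baseline.mean_counts_per_channel)


def relative_percentages(net_areas) -> np.ndarray:
    """Shares of total net peak area in percent; negatives clamped to 0.

    Raises :class:`UndefinedPercentageError` when no area is positive.
    """
    areas = np.asarray(net_areas, dtype=float)
    if areas.size == 0:
        raise UndefinedPercentageError("no peak regions")
    if np.any(areas < 0):
        warnings.warn(
            "negative net area(s) clamped to 0 before normalization",
            stacklevel=2,
        )
    clamped = np.clip(areas, 0.0, None)
    total = clamped.sum()
    if total <= 0:
        raise UndefinedPercentageError(
            "all net areas are <= 0; percentages undefined"
        )
    return 100.0 * (clamped / total)


def retention_factor(peak_position_mm: float, origin_mm: float, front_mm: float) -> float:
    """Rf = (peak - origin) / (front - origin)."""
    if front_mm <= origin_mm:
        raise InvalidMarksError(
            f"front mark ({front_mm}) must lie beyond origin ({origin_mm})"
        )
    rf = (peak_position_mm - origin_mm) / (front_mm - origin_mm)
    if not -0.05 <= rf <= 1.05:
        warnings.warn(f"Rf = {rf:.3f} falls outside the strip", stacklevel=2)
    return rf


def snr(peak_height_net: float, noise_pp: float) -> float:
    """Pharmacopoeial SNR = 2H/h (background-subtracted height over
    peak-to-peak baseline noise)."""
    if noise_pp < 0:
        raise InsufficientBaselineError("noise must be >= 0")
    if noise_pp == 0:
        warnings.warn("zero baseline noise; SNR is infinite", stacklevel=2)
        return math.inf
    return 2.0 * peak_height_net / noise_pp


def _interp_crossing(x0, y0, x1, y1, level):
    if y1 == y0:
        return x0
    return x0 + (level - y0) * (x1 - x0) / (y1 - y0)


def fwhm(chromatogram: Chromatogram, region: Region, baseline: BaselineStats) -> float:
    """Width between the half-maximum crossings of the net profile (mm).

    Crossings are located by linear interpolation between adjacent
    channels; for a Gaussian of parameter sigma this returns
    ``2.3548 * sigma`` within one channel pitch.
    """
    mask = region_mask(chromatogram, region)
    pos = chromatogram.positions_mm[mask]
    net = chromatogram.counts[mask] - baseline.mean_counts_per_channel
    if len(net) == 0:
        raise UndefinedFWHMError(f"region {region.label!r} contains no channels")
    i_max = int(np.argmax(net))  # argmax takes the first (lowest-position) tie
    height = net[i_max]
    if height <= 0:
        raise UndefinedFWHMError(
            f"region {region.label!r}: peak not above baseline"
        )
    half = height / 2.0

    left = None
    for i in range(i_max - 1, -1, -1):
        if net[i] <= half:
            left = _interp_crossing(pos[i], net[i], pos[i + 1], net[i + 1], half)
            break
    right = None
    for i in range(i_max + 1, len(net)):
        if net[i] <= half:
            right = _interp_crossing(pos[i - 1], net[i - 1], pos[i], net[i], half)
            break
    if left is None or right is None:
        raise UndefinedFWHMError(
            f"region {region.label!r}: half-maximum crossing outside region"
        )
    return float(right - left)


def analyze_strip(
    record: AcquisitionRecord | Chromatogram,
    region_set: RegionSet,
    main_label: str | None = None,
) -> AnalysisReport:
    """Full per-region analysis of one strip.

    ``main_label`` names the peak region of the desired species; when
    omitted the region with the largest net area is taken as the main
    species.  Records whose footprint verification failed are refused.
    """
    chromatogram = (
        record.chromatogram if isinstance(record, AcquisitionRecord) else record
    )
    if chromatogram.integrity == "failed":
        raise IntegrityError(
            "record failed SHA-256 verification; refusing to analyze"
        )
    baseline = baseline_stats(chromatogram, region_set.background)
    peaks = region_set.peaks
    net_areas = [integrate_region(chromatogram, r, baseline) for r in peaks]
    percents = relative_percentages(net_areas)

    meta = chromatogram.metadata
    results = []
    for region, area, percent in zip(peaks, net_areas, percents):
        mask = region_mask(chromatogram, region)
        pos = chromatogram.positions_mm[mask]
        net = chromatogram.counts[mask] - baseline.mean_counts_per_channel
        i_max = int(np.argmax(net))
        peak_pos = float(pos[i_max])
        height = float(net[i_max])
        try:
            width = fwhm(chromatogram, region, baseline)
        except UndefinedFWHMError:
            width = None
        results.append(
            PeakResult(
                label=region.label,
                net_area_counts=area,
                percent=float(percent),
                rf=retention_factor(peak_pos, meta.origin_mm, meta.front_mm),
                snr=snr(height, baseline.noise_pp_counts),
                fwhm_mm=width,
                peak_position_mm=peak_pos,
                peak_height_counts=height,
            )
        )

    if main_label is None:
        main = max(results, key=lambda p: p.net_area_counts)
    else:
        by_label = {p.label: p for p in results}
        if main_label not in by_label:
            raise RegionBoundsError(
                f"main species label {main_label!r} not among peak regions"
            )
        main = by_label[main_label]
    return AnalysisReport(
        peaks=tuple(results),
        baseline=baseline,
        rcp_percent=main.percent,
        main_label=main.label,
        integrity_status=chromatogram.integrity,
    )


def rcp_dual_strip(report_strip1: AnalysisReport, report_strip2: AnalysisReport) -> float:
    """Overall RCP of a dual-strip assay: 100 - impurity1% - impurity2%."""
    rcp = 100.0 - report_strip1.impurity_percent - report_strip2.impurity_percent
    if rcp < 0:
        warnings.warn(
            "impurity percentages exceed 100%; overall RCP clamped to 0",
            stacklevel=2,
        )
        return 0.0
    return rcp


# --- region-set CSV (label,start_mm,end_mm,kind) -------------------------

_REGION_HEADER = "label,start_mm,end_mm,kind"


def read_regions(path: str | Path) -> RegionSet:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    lines = [ln for ln in lines if ln.strip() and not ln.startswith("#")]
    if not lines or lines[0].strip() != _REGION_HEADER:
        raise ParseError(f"region file must start with header {_REGION_HEADER!r}", 1)
    regions = []
    for i, line in enumerate(lines[1:], start=2):
        parts = [p.strip() for p in line.split(",")]
        if len(parts) != 4:
            raise ParseError(f"expected 4 fields, got {len(parts)}", i)
        label, start_text, end_text, kind = parts
        try:
            start, end = float(start_text), float(end_text)
        except ValueError:
            raise ParseError(f"non-numeric bounds in {line!r}", i) from None
        regions.append(Region(label=label, start_mm=start, end_mm=end, kind=kind))
    return RegionSet(tuple(regions))


def write_regions(region_set: RegionSet, path: str | Path) -> None:
    lines = [_REGION_HEADER]
    for r in region_set.regions:
        lines.append(f"{r.label},{r.start_mm},{r.end_mm},{r.kind}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
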