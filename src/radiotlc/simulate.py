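"""Detector and scan simulator.

Emulates a collimated scintillation detector stepping along a TLC strip:
spots of activity on the strip, exponential radioactive decay, a Gaussian
line-spread response for the collimator slit, and Poisson counting per
channel dwell.  The simulator is the sole source of test inputs for the
analysis and qualification layers; it replaces the physical instrument.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidParameterError

__all__ = [
    "TC99M_HALF_LIFE_H",
    "DEFAULT_EFFICIENCY_CPS_PER_MBQ",
    "DEFAULT_BACKGROUND_CPS",
    "DEFAULT_RESPONSE_SIGMA_MM",
    "SCAN_RANGE_LIMIT_MM",
    "SpotDeposit",
    "StripModel",
    "ScanConfig",
    "AcquisitionMetadata",
    "Chromatogram",
    "decay_activity",
    "channel_positions",
    "line_spread_weight",
    "expected_rate",
    "simulate_scan",
    "make_scenario",
    "linearity_offsets_h",
    "SCENARIO_NAMES",
]

#: Half-life of technetium-99m in hours.
TC99M_HALF_LIFE_H = 6.0067

#: Default whole-spot detection efficiency (counts/s per MBq summed over
#: all channels).  Calibrated so a 0.4 MBq spot accumulates ~1e3 counts in
#: a 2-minute scan.
DEFAULT_EFFICIENCY_CPS_PER_MBQ = 5000.0

#: Default background count rate per channel dwell (counts/s).
DEFAULT_BACKGROUND_CPS = 0.31

#: Default detector line-spread standard deviation (mm); a point deposit
#: then shows FWHM = 2.3548 * sigma = 3.5 mm.
DEFAULT_RESPONSE_SIGMA_MM = 1.486

#: Hard software limit on the scanned length (mm).
SCAN_RANGE_LIMIT_MM = 120.0

_GAUSS_NORM = 1.0 / math.sqrt(2.0 * math.pi)


@dataclass(frozen=True)
class SpotDeposit:
    """A radioactive spot applied to the strip.

    Parameters
    ----------
    position_mm
        Spot center in strip coordinates (mm from scan start).
    activity_MBq
        Activity at reference time zero.
    deposit_sigma_mm
        Physical spread of the applied drop (Gaussian sigma, mm).
    """

    position_mm: float
    activity_MBq: float
    deposit_sigma_mm: float = 0.0

    def __post_init__(self):
        if self.activity_MBq < 0:
            raise InvalidParameterError("spot activity must be >= 0")
        if self.deposit_sigma_mm < 0:
            raise InvalidParameterError("deposit sigma must be >= 0")


@dataclass(frozen=True)
class StripModel:
    """Physical truth of one strip: deposits plus solvent marks."""

    length_mm: float
    spots: tuple[SpotDeposit, ...] = ()
    origin_mm: float = 0.0
    front_mm: float | None = None

    def __post_init__(self):
        if self.length_mm <= 0:
            raise InvalidParameterError("strip length must be > 0")
        object.__setattr__(self, "spots", tuple(self.spots))
        front = self.length_mm if self.front_mm is None else self.front_mm
        object.__setattr__(self, "front_mm", float(front))
        if not (0 <= self.origin_mm < self.front_mm <= self.length_mm):
            raise InvalidParameterError(
                "marks must satisfy 0 <= origin < front <= length "
                f"(origin={self.origin_mm}, front={self.front_mm}, "
                f"length={self.length_mm})"
            )
        for spot in self.spots:
            if not (0 <= spot.position_mm <= self.length_mm):
                raise InvalidParameterError(
                    f"spot at {spot.position_mm} mm lies outside the strip"
                )


@dataclass(frozen=True)
class ScanConfig:
    """Instrument parameters for one acquisition."""

    scan_range_mm: float
    total_time_s: float
    step_mm: float = 0.5
    efficiency_cps_per_MBq: float = DEFAULT_EFFICIENCY_CPS_PER_MBQ
    background_cps: float = DEFAULT_BACKGROUND_CPS
    response_sigma_mm: float = DEFAULT_RESPONSE_SIGMA_MM
    half_life_h: float = TC99M_HALF_LIFE_H
    start_offset_h: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.scan_range_mm <= SCAN_RANGE_LIMIT_MM:
            raise InvalidParameterError(
                f"scan range must be in (0, {SCAN_RANGE_LIMIT_MM}] mm "
                f"(software safety limit), got {self.scan_range_mm}"
            )
        if self.step_mm <= 0:
            raise InvalidParameterError("step must be > 0")
        if self.total_time_s <= 0:
            raise InvalidParameterError("total acquisition time must be > 0")
        if self.efficiency_cps_per_MBq < 0:
            raise InvalidParameterError("efficiency must be >= 0")
        if self.background_cps < 0:
            raise InvalidParameterError("background rate must be >= 0")
        if self.response_sigma_mm < 0:
            raise InvalidParameterError("response sigma must be >= 0")
        if self.half_life_h <= 0:
            raise InvalidParameterError("half-life must be > 0")
        if self.start_offset_h < 0:
            raise InvalidParameterError("start offset must be >= 0")

    def replace(self, **changes) -> "ScanConfig":
        return replace(self, **changes)


_META_TEXT_FIELDS = ("batch_number", "operator", "timestamp")


@dataclass(frozen=True)
class AcquisitionMetadata:
    """Header block saved with every acquisition record."""

    batch_number: str
    operator: str
    scan_range_mm: float
    acquisition_time_s: float
    origin_mm: float
    front_mm: float
    timestamp: str
    extra: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        if self.origin_mm >= self.front_mm:
            raise InvalidParameterError("origin mark must precede front mark")
        if self.acquisition_time_s <= 0:
            raise InvalidParameterError("acquisition time must be > 0")
        for name in _META_TEXT_FIELDS:
            value = getattr(self, name)
            if "\n" in value or "\r" in value:
                raise InvalidParameterError(f"{name} must not contain newlines")
        object.__setattr__(self, "extra", tuple(self.extra))
        for key, value in self.extra:
            for part in (key, value):
                if "\n" in part or "\r" in part:
                    raise InvalidParameterError("metadata must not contain newlines")


@dataclass
class Chromatogram:
    """One acquisition: channel positions, integer counts, dwell, metadata."""

    positions_mm: np.ndarray
    counts: np.ndarray
    dwell_s: float
    metadata: AcquisitionMetadata
    integrity: str = "unhashed"

    def __post_init__(self):
        self.positions_mm = np.asarray(self.positions_mm, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.counts.dtype.kind not in "iu":
            rounded = np.rint(self.counts)
            if not np.array_equal(rounded, self.counts):
                raise InvalidParameterError("counts must be integers")
            self.counts = rounded.astype(np.int64)
        else:
            self.counts = self.counts.astype(np.int64)
        if self.positions_mm.ndim != 1 or self.counts.ndim != 1:
            raise InvalidParameterError("positions and counts must be 1-D")
        if len(self.positions_mm) != len(self.counts):
            raise InvalidParameterError("positions and counts differ in length")
        if len(self.positions_mm) == 0:
            raise InvalidParameterError("chromatogram must have >= 1 channel")
        if np.any(self.counts < 0):
            raise InvalidParameterError("counts must be >= 0")
        if self.dwell_s <= 0:
            raise InvalidParameterError("dwell time must be > 0")
        diffs = np.diff(self.positions_mm)
        if len(diffs) > 0:
            if np.any(diffs <= 0):
                raise InvalidParameterError("positions must be strictly increasing")
            if not np.allclose(diffs, diffs[0], rtol=1e-9, atol=1e-9):
                raise InvalidParameterError("positions must have constant pitch")
        if self.integrity not in ("verified", "failed", "unhashed"):
            raise InvalidParameterError(f"unknown integrity state {self.integrity!r}")

    @property
    def n_channels(self) -> int:
        return len(self.positions_mm)

    @property
    def step_mm(self) -> float:
        if len(self.positions_mm) < 2:
            return float("nan")
        return float(self.positions_mm[1] - self.positions_mm[0])

    @property
    def total_time_s(self) -> float:
        return self.dwell_s * self.n_channels

    @property
    def total_counts(self) -> int:
        return int(self.counts.sum())


def decay_activity(a0_MBq: float, elapsed_h: float, half_life_h: float) -> float:
    """Exponentially decayed activity ``a0 * 2**(-elapsed / half_life)``."""
    if a0_MBq < 0:
        raise InvalidParameterError("initial activity must be >= 0")
    if elapsed_h < 0:
        raise InvalidParameterError("elapsed time must be >= 0")
    if half_life_h <= 0:
        raise InvalidParameterError("half-life must be > 0")
    return a0_MBq * 2.0 ** (-elapsed_h / half_life_h)


def channel_positions(config: ScanConfig) -> np.ndarray:
    """Channel centers at ``(i + 1/2) * step`` for ``i = 0 .. n-1``.

    ``n = floor(scan_range / step)``; 240 channels for a 120 mm range at
    0.5 mm pitch.
    """
    if config.step_mm > config.scan_range_mm:
        raise InvalidParameterError(
            f"step ({config.step_mm} mm) exceeds scan range "
            f"({config.scan_range_mm} mm)"
        )
    n = int(math.floor(config.scan_range_mm / config.step_mm + 1e-9))
    return (np.arange(n) + 0.5) * config.step_mm


def line_spread_weight(distance_mm, response_sigma_mm: float, step_mm: float):
    """Fraction of a point source's rate seen by a channel at ``distance``.

    Gaussian line-spread sampled at the channel pitch:
    ``w = step * N(distance; 0, sigma)``.  Summed over a channel grid the
    weights approach 1 (Riemann sum of a unit-area density).  ``sigma = 0``
    uses the delta convention: full weight on the nearest channel.
    """
    if response_sigma_mm < 0:
        raise InvalidParameterError("response sigma must be >= 0")
    if step_mm <= 0:
        raise InvalidParameterError("step must be > 0")
    d = np.asarray(distance_mm, dtype=float)
    if response_sigma_mm == 0:
        w = np.where(np.abs(d) <= step_mm / 2.0, 1.0, 0.0)
    else:
        z = d / response_sigma_mm
        w = step_mm / response_sigma_mm * _GAUSS_NORM * np.exp(-0.5 * z * z)
    return w if w.ndim else float(w)


def _effective_sigma(config: ScanConfig, spot: SpotDeposit) -> float:
    return math.hypot(config.response_sigma_mm, spot.deposit_sigma_mm)


def expected_rate(
    model: StripModel,
    config: ScanConfig,
    position_mm: float,
    elapsed_h: float = 0.0,
) -> float:
    """Expected count rate (cps) at a channel position and elapsed time.

    ``background + sum_k eff * decay(A_k) * w(position - mu_k; sigma_eff)``
    with ``sigma_eff**2 = response_sigma**2 + deposit_sigma**2``.
    """
    rate = config.background_cps
    for spot in model.spots:
        activity = decay_activity(spot.activity_MBq, elapsed_h, config.half_life_h)
        weight = line_spread_weight(
            position_mm - spot.position_mm,
            _effective_sigma(config, spot),
            config.step_mm,
        )
        rate += config.efficiency_cps_per_MBq * activity * weight
    return rate


def _expected_rates(
    model: StripModel, config: ScanConfig, positions: np.ndarray, elapsed_h: np.ndarray
) -> np.ndarray:
    rates = np.full(len(positions), config.background_cps, dtype=float)
    for spot in model.spots:
        activity = spot.activity_MBq * 2.0 ** (-elapsed_h / config.half_life_h)
        weight = line_spread_weight(
            positions - spot.position_mm,
            _effective_sigma(config, spot),
            config.step_mm,
        )
        rates += config.efficiency_cps_per_MBq * activity * weight
    return rates


#: Fixed timestamp used by default so simulated records are byte-reproducible.
DEFAULT_TIMESTAMP = "2025-01-01T00:00:00"


def simulate_scan(
    model: StripModel,
    config: ScanConfig,
    *,
    batch_number: str = "SIM",
    operator: str = "simulator",
    timestamp: str = DEFAULT_TIMESTAMP,
    extra_metadata: tuple[tuple[str, str], ...] = (),
    noiseless: bool = False,
) -> Chromatogram:
    """Simulate one scan of ``model`` under ``config``.

    Counts per channel are Poisson with mean ``dwell * expected_rate``; the
    rate for channel ``i`` is evaluated at elapsed time
    ``start_offset + i * dwell / 3600`` so decay during the scan is modeled.
    Identical (model, config) including seed yields identical output.

    With ``noiseless=True`` the Poisson draw is replaced by the rounded
    expectation (deterministic, for oracles and demonstrations).
    """
    positions = channel_positions(config)
    n = len(positions)
    if n == 0:
        raise InvalidParameterError("configuration yields zero channels")
    dwell = config.total_time_s / n
    elapsed = config.start_offset_h + np.arange(n) * dwell / 3600.0
    means = dwell * _expected_rates(model, config, positions, elapsed)
    if noiseless:
        counts = np.rint(means).astype(np.int64)
    else:
        rng = np.random.default_rng(config.seed)
        counts = rng.poisson(means)
    metadata = AcquisitionMetadata(
        batch_number=batch_number,
        operator=operator,
        scan_range_mm=config.scan_range_mm,
        acquisition_time_s=config.total_time_s,
        origin_mm=model.origin_mm,
        front_mm=model.front_mm,
        timestamp=timestamp,
        extra=extra_metadata,
    )
    return Chromatogram(positions, counts, dwell, metadata, integrity="unhashed")


def linearity_offsets_h(
    a0_MBq: float = 18.5,
    a_end_MBq: float = 0.0025,
    half_life_h: float = TC99M_HALF_LIFE_H,
    n: int = 9,
) -> np.ndarray:
    """Elapsed times (h) evenly spanning decay from ``a0`` to ``a_end``."""
    if not 0 < a_end_MBq < a0_MBq:
        raise InvalidParameterError("need 0 < a_end < a0")
    t_end = math.log2(a0_MBq / a_end_MBq) * half_life_h
    return np.linspace(0.0, t_end, n)


SCENARIO_NAMES = (
    "background",
    "linearity",
    "repeatability",
    "loq",
    "position_accuracy",
    "comparison_pair",
)


def make_scenario(name: str, **kwargs) -> tuple[StripModel, ScanConfig]:
    """Factory for the published qualification geometries.

    ``background``
        blank 120 mm strip, 300 s acquisition.
    ``linearity``
        single 18.5 MBq spot at strip center, 120 s; combine with
        :func:`linearity_offsets_h` for the nine-point decay series.
    ``repeatability``
        7.4 MBq and 0.4 MBq spots at opposite ends (5% impurity design),
        120 s.
    ``loq``
        single spot of activity ``activity_MBq`` (default 0.0025), 300 s.
    ``position_accuracy``
        nine equal spots at 10 mm spacing on a 100 mm strip.
    ``comparison_pair``
        main + impurity strip totalling 7.8 MBq with impurity share
        ``impurity_percent`` (default 5.0), 120 s.

    Additional keyword arguments override :class:`ScanConfig` fields
    (``seed`` in particular).
    """
    activity = kwargs.pop("activity_MBq", 0.0025)
    impurity_percent = kwargs.pop("impurity_percent", 5.0)

    if name == "background":
        model = StripModel(length_mm=120.0, spots=(), origin_mm=10.0, front_mm=110.0)
        config = ScanConfig(scan_range_mm=120.0, total_time_s=300.0)
    elif name == "linearity":
        model = StripModel(
            length_mm=120.0,
            spots=(SpotDeposit(position_mm=60.0, activity_MBq=18.5),),
            origin_mm=10.0,
            front_mm=110.0,
        )
        config = ScanConfig(scan_range_mm=120.0, total_time_s=120.0)
    elif name == "repeatability":
        model = StripModel(
            length_mm=120.0,
            spots=(
                SpotDeposit(position_mm=20.0, activity_MBq=7.4),
                SpotDeposit(position_mm=100.0, activity_MBq=0.4),
            ),
            origin_mm=10.0,
            front_mm=110.0,
        )
        config = ScanConfig(scan_range_mm=120.0, total_time_s=120.0)
    elif name == "loq":
        model = StripModel(
            length_mm=120.0,
            spots=(SpotDeposit(position_mm=60.0, activity_MBq=activity),),
            origin_mm=10.0,
            front_mm=110.0,
        )
        config = ScanConfig(scan_range_mm=120.0, total_time_s=300.0)
    elif name == "position_accuracy":
        spots = tuple(
            SpotDeposit(position_mm=10.0 * (k + 1), activity_MBq=0.5)
            for k in range(9)
        )
        model = StripModel(length_mm=100.0, spots=spots, origin_mm=0.0, front_mm=100.0)
        config = ScanConfig(scan_range_mm=100.0, total_time_s=120.0)
    elif name == "comparison_pair":
        impurity_MBq = 7.8 * impurity_percent / 100.0
        model = StripModel(
            length_mm=120.0,
            spots=(
                SpotDeposit(position_mm=20.0, activity_MBq=7.8 - impurity_MBq),
                SpotDeposit(position_mm=100.0, activity_MBq=impurity_MBq),
            ),
            origin_mm=10.0,
            front_mm=110.0,
        )
        config = ScanConfig(scan_range_mm=120.0, total_time_s=120.0)
    else:
        raise InvalidParameterError(
            f"unknown scenario {name!r}; valid scenarios: "
            + ", ".join(SCENARIO_NAMES)
        )
    if kwargs:
        config = config.replace(**kwargs)
    return model, config
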