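import numpy as np
import pytest

from radiotlc.simulate import (
    AcquisitionMetadata,
    Chromatogram,
    ScanConfig,
    SpotDeposit,
    StripModel,
)


@pytest.fixture
def default_config():
    return ScanConfig(scan_range_mm=120.0, total_time_s=120.0, seed=42)


@pytest.fixture
def blank_strip():
    return StripModel(length_mm=120.0, spots=(), origin_mm=10.0, front_mm=110.0)


@pytest.fixture
def single_spot_strip():
    return StripModel(
        length_mm=120.0,
        spots=(SpotDeposit(position_mm=60.0, activity_MBq=1.0),),
        origin_mm=10.0,
        front_mm=110.0,
    )


def make_metadata(**overrides):
    defaults = dict(
        batch_number="B001",
        operator="tester",
        scan_range_mm=120.0,
        acquisition_time_s=120.0,
        origin_mm=10.0,
        front_mm=110.0,
        timestamp="2025-01-01T00:00:00",
    )
    defaults.update(overrides)
    return AcquisitionMetadata(**defaults)


def make_chromatogram(counts, step_mm=0.5, dwell_s=0.5, **meta_overrides):
    counts = np.asarray(counts)
    positions = (np.arange(len(counts)) + 0.5) * step_mm
    meta_overrides.setdefault("scan_range_mm", len(counts) * step_mm)
    meta_overrides.setdefault("acquisition_time_s", dwell_s * len(counts))
    meta_overrides.setdefault(
        "front_mm", min(110.0, len(counts) * step_mm)
    )
    meta_overrides.setdefault("origin_mm", 0.0)
    return Chromatogram(
        positions_mm=positions,
        counts=counts,
        dwell_s=dwell_s,
        metadata=make_metadata(**meta_overrides),
    )


@pytest.fixture
def gaussian_chromatogram():
    """Noiseless Gaussian peak (sigma 1.486 mm) on a flat baseline of 100."""

    def build(sigma_mm=1.486, amplitude=100000.0, baseline=100, step_mm=0.5, n=240):
        positions = (np.arange(n) + 0.5) * step_mm
        center = positions[n // 2]
        profile = amplitude * np.exp(-0.5 * ((positions - center) / sigma_mm) ** 2)
        counts = np.rint(profile + baseline).astype(np.int64)
        return make_chromatogram(counts, step_mm=step_mm), center

    return build
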