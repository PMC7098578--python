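"""Descriptors of within-plot individual grain-size distributions and the
computed yield components.

Each harvested micro-plot contributes a bulk of 300-500 individual grain
projected areas (mm^2, a proxy for single-grain mass).  The distribution is
summarised by its mean (GSM), sample variance (GSV), and 5th/95th
percentiles (P5/P95).  From the directly measured plot traits -- grain yield
GY (t/ha at 15% humidity), spikes per m^2 (SPM2) and thousand-kernel weight
TKW (g at 15% humidity) -- the grain numbers per m^2 (GPM2) and per spike
(GPS) are derived.

Conventions (documented because the raw values depend on them): GSV uses the
unbiased n-1 denominator; percentiles use linear interpolation between order
statistics (numpy's default, Hyndman-Fan type 7).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GrainSample",
    "GrainDistributionMetrics",
    "YieldComponents",
    "grain_descriptors",
    "to_15pc_humidity",
    "to_dry_mass",
    "derive_components",
    "metrics_table",
    "read_grain_csv",
]


class InsufficientSampleError(ValueError):
    """Fewer than two grains: variance undefined."""


@dataclass(frozen=True)
class GrainSample:
    plot_id: str
    areas: np.ndarray  # projected areas, mm^2, all > 0

    def validate(self) -> None:
        areas = np.asarray(self.areas, dtype=float)
        if areas.size < 2:
            raise InsufficientSampleError(
                f"plot {self.plot_id}: need >= 2 grains, got {areas.size}"
            )
        if not np.all(areas > 0):
            raise ValueError(f"plot {self.plot_id}: non-positive grain area")


@dataclass(frozen=True)
class GrainDistributionMetrics:
    plot_id: str
    gsm: float     # mean area, mm^2
    gsv: float     # sample variance, mm^4
    p5: float      # 5th percentile, mm^2
    p95: float     # 95th percentile, mm^2
    n_grains: int


@dataclass(frozen=True)
class YieldComponents:
    gy: float    # t/ha, 15% humidity
    spm2: float  # spikes per m^2
    tkw: float   # g per 1000 grains, 15% humidity
    gpm2: float  # grains per m^2
    gps: float   # grains per spike


def grain_descriptors(sample: GrainSample) -> GrainDistributionMetrics:
    """Mean, sample variance and 5th/95th percentiles of one grain bulk."""
    sample.validate()
    areas = np.asarray(sample.areas, dtype=float)
    p5, p95 = np.percentile(areas, [5.0, 95.0])  # type-7 linear interpolation
    return GrainDistributionMetrics(
        plot_id=sample.plot_id,
        gsm=float(areas.mean()),
        gsv=float(areas.var(ddof=1)),
        p5=float(p5),
        p95=float(p95),
        n_grains=int(areas.size),
    )


def to_15pc_humidity(dry_mass: float, moisture_target: float = 0.15) -> float:
    """Express a dry grain mass on a notional moisture basis (default 15%)."""
    if not 0.0 <= moisture_target < 1.0:
        raise ValueError("moisture_target must be in [0, 1)")
    if dry_mass < 0:
        raise ValueError("dry_mass must be >= 0")
    return dry_mass / (1.0 - moisture_target)


def to_dry_mass(wet_mass: float, moisture_target: float = 0.15) -> float:
    """Inverse of :func:`to_15pc_humidity`."""
    if not 0.0 <= moisture_target < 1.0:
        raise ValueError("moisture_target must be in [0, 1)")
    return wet_mass * (1.0 - moisture_target)


def derive_components(gy: float, spm2: float, tkw: float) -> YieldComponents:
    """Grain numbers from yield, spike density and kernel weight.

    GY in t/ha equals 100 g/m^2, so GPM2 = (gy * 100) / (tkw / 1000) and
    GPS = GPM2 / SPM2.  A zero yield maps to zero grain numbers.
    """
    if spm2 <= 0 or tkw <= 0:
        raise ZeroDivisionError("spm2 and tkw must be positive")
    if gy < 0:
        raise ValueError("gy must be >= 0")
    gpm2 = (gy * 100.0) / (tkw / 1000.0)
    gps = gpm2 / spm2
    return YieldComponents(gy=gy, spm2=spm2, tkw=tkw, gpm2=gpm2, gps=gps)


def read_grain_csv(path) -> pd.DataFrame:
    """Read a long grain table (plot_id, area_mm2)."""
    df = pd.read_csv(path)
    missing = {"plot_id", "area_mm2"} - set(df.columns)
    if missing:
        raise ValueError(f"grain table missing columns: {sorted(missing)}")
    return df


def metrics_table(grains: pd.DataFrame) -> pd.DataFrame:
    """Per-plot grain-distribution metrics from a long (plot_id, area_mm2) table.

    Also emits the standard deviation sqrt(GSV), used when comparing
    coefficients of variation on the SD rather than the variance scale.
    """
    rows = []
    for plot_id, grp in grains.groupby("plot_id", sort=False):
        m = grain_descriptors(GrainSample(str(plot_id), grp["area_mm2"].to_numpy()))
        rows.append(
            {
                "plot_id": plot_id,
                "GSM": m.gsm,
                "GSV": m.gsv,
                "GSD": float(np.sqrt(m.gsv)),
                "P5": m.p5,
                "P95": m.p95,
                "n_grains": m.n_grains,
            }
        )
    return pd.DataFrame(rows)
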