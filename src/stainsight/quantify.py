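"""Area-ratio cell counting, density classes and transport efficiency.

One focal-plane image rarely shows separable single cells once the magnet
has piled conjugates up, so the cell number is estimated as the ratio of the
total area occupied by conjugates to the average area of a single cell.
Comparing the first and last chip compartments gives the conjugate transport
efficiency, whose complement is the conjugate loss in magnet transit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ConfigurationError, SampleSizeError
from .segmentation import SegmentedObject

DENSITY_LABELS = ("high", "medium", "low", "ultra_low")

#: Counts above this are "high" density; strictly between the two bounds is
#: "medium"; below the medium bound is "low".
HIGH_MIN = 50_000
MEDIUM_MIN = 30_000
#: Sub-threshold regime for near-detection-floor runs (configurable).
ULTRA_LOW_MAX_DEFAULT = 1_000

#: Regions larger than this multiple of the median single-object area are
#: treated as merged clusters, not single cells.
CLUSTER_CUTOFF_FACTOR = 1.6


def classify_density(count: float, ultra_low_max: float = ULTRA_LOW_MAX_DEFAULT) -> str:
    """Bin an estimated cell count into the chip's density classes.

    Boundary counts (exactly 30,000 or 50,000) fall to the lower class.
    """
    if count < 0:
        raise ConfigurationError("count must be non-negative")
    if count <= ultra_low_max:
        return "ultra_low"
    if count <= MEDIUM_MIN:
        return "low"
    if count <= HIGH_MIN:
        return "medium"
    return "high"


@dataclass(frozen=True)
class CompartmentReport:
    """Area-ratio count estimate for one compartment image."""

    compartment: str
    total_conjugate_area_px: float
    mean_cell_area_px: float
    estimated_count: float
    density: str
    pixel_scale: float | None = None

    def to_dict(self) -> dict:
        return {
            "compartment": self.compartment,
            "total_conjugate_area_px": self.total_conjugate_area_px,
            "mean_cell_area_px": self.mean_cell_area_px,
            "estimated_count": self.estimated_count,
            "density": self.density,
            "pixel_scale": self.pixel_scale,
        }


def mean_cell_area(
    objects: Sequence[SegmentedObject],
    cluster_cutoff_factor: float = CLUSTER_CUTOFF_FACTOR,
) -> float:
    """Mean area of single-cell regions, excluding merged clusters.

    A region is a cluster when its area exceeds ``cluster_cutoff_factor``
    times the median region area (two merged cells roughly double the area,
    so the default 1.6 separates singles from clusters in monodisperse
    fields).
    """
    if not objects:
        raise SampleSizeError(
            "no objects to average; supply mean_cell_area_px manually"
        )
    areas = np.asarray([o.area_px for o in objects], dtype=float)
    cutoff = cluster_cutoff_factor * float(np.median(areas))
    singles = areas[areas <= cutoff]
    if singles.size == 0:
        raise SampleSizeError(
            "no single-cell regions below the cluster cutoff; "
            "supply mean_cell_area_px manually"
        )
    return float(singles.mean())


def estimate_count(
    objects: Sequence[SegmentedObject],
    mean_cell_area_px: float,
    compartment: str = "unlabeled",
    ultra_low_max: float = ULTRA_LOW_MAX_DEFAULT,
    pixel_scale: float | None = None,
) -> CompartmentReport:
    """Estimate the focal-plane cell number as total area / single-cell area."""
    if mean_cell_area_px <= 0:
        raise ConfigurationError("mean_cell_area_px must be > 0")
    total = float(sum(o.area_px for o in objects))
    count = total / mean_cell_area_px
    return CompartmentReport(
        compartment=compartment,
        total_conjugate_area_px=total,
        mean_cell_area_px=float(mean_cell_area_px),
        estimated_count=count,
        density=classify_density(count, ultra_low_max=ultra_low_max),
        pixel_scale=pixel_scale,
    )


@dataclass(frozen=True)
class EfficiencyResult:
    """First-to-last compartment transport efficiency and conjugate loss."""

    efficiency_pct: float
    loss_pct: float
    over_100: bool

    def to_dict(self) -> dict:
        return {
            "efficiency_pct": self.efficiency_pct,
            "loss_pct": self.loss_pct,
            "over_100": self.over_100,
        }


def transport_efficiency(
    first: CompartmentReport | float, last: CompartmentReport | float
) -> EfficiencyResult:
    """``100 * last / first`` percent; loss is the exact complement.

    Values above 100% (a last compartment apparently richer than the first)
    are flagged, not clamped.
    """
    f = first.estimated_count if isinstance(first, CompartmentReport) else float(first)
    l = last.estimated_count if isinstance(last, CompartmentReport) else float(last)
    if f <= 0:
        raise ConfigurationError("first-compartment count must be > 0")
    eff = 100.0 * l / f
    return EfficiencyResult(
        efficiency_pct=eff, loss_pct=100.0 - eff, over_100=bool(eff > 100.0)
    )


@dataclass(frozen=True)
class LinearityResult:
    slope: float
    intercept: float
    r_squared: float
    verdict: str  # "linear" | "non_linear"

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "verdict": self.verdict,
        }


def linearity_check(
    points: Sequence[tuple[float, float]], r2_threshold: float = 0.95
) -> LinearityResult:
    """Least-squares fit of estimated counts against input cell numbers.

    The assay counts linearly over its working range when r^2 meets the
    threshold (default 0.95).
    """
    if len(points) < 3:
        raise ConfigurationError("need at least 3 points for a linearity check")
    x = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    if np.ptp(y) == 0.0:
        return LinearityResult(0.0, float(y[0]), 0.0, "non_linear")
    fit = stats.linregress(x, y)
    r2 = float(fit.rvalue**2)
    return LinearityResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r2,
        verdict="linear" if r2 >= r2_threshold else "non_linear",
    )
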