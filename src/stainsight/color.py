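"""Per-band difference-from-background statistics and stain classification.

The core statistic is the per-band deficit ``d_c = background_c - object_c``
for ``c in {R, G, B}``: a dark object on a bright field has positive deficits
in every band, and the dye's own hue is the *dominant* band — the brightest
one, i.e. the band with the smallest deficit.  Classes are told apart with a
two-stage rule: a minimum-deficit gate against the background, then per-band
interval checks with nearest-profile assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SampleSizeError
from .segmentation import BackgroundEstimate, SegmentedObject
from .synthetic import BANDS, STAIN_PROFILES, STAINED_CLASSES, Band, StainProfile


@dataclass(frozen=True)
class BandDifferences:
    """Per-band deficit of one object from the background (signed, unclamped)."""

    d_rgb: tuple[float, float, float]
    source_label: int | None = None

    @property
    def d(self) -> np.ndarray:
        return np.asarray(self.d_rgb, dtype=float)


def band_differences(
    obj: SegmentedObject, bg: BackgroundEstimate
) -> BandDifferences:
    """Exact per-band subtraction ``background mean - object mean``."""
    d = bg.mean - np.asarray(obj.mean_rgb, dtype=float)
    return BandDifferences(d_rgb=tuple(d), source_label=obj.label)


def dominant_band(d: BandDifferences) -> tuple[Band, bool]:
    """Band with the smallest deficit (the dye's own color stays brightest).

    Ties are broken in R > G > B priority; the second return value flags a
    tie so ambiguous calls are visible downstream.
    """
    arr = d.d
    i = int(np.argmin(arr))
    tie = bool(np.sum(arr == arr[i]) > 1)
    return BANDS[i], tie


@dataclass(frozen=True)
class ClassificationRule:
    """Two-stage threshold rule over band deficits.

    Stage 1 rejects anything whose smallest deficit is below
    ``stage1_min_deficit`` (background).  Stage 2 keeps classes whose
    per-band intervals all contain the observed deficit and assigns the
    nearest class centre in Euclidean d-space; no interval match yields
    ``"unknown"``.
    """

    stage1_min_deficit: float
    intervals: Mapping[str, tuple[tuple[float, float], ...]]
    centers: Mapping[str, tuple[float, float, float]]

    REJECT: str = field(default="background", init=False)
    UNKNOWN: str = field(default="unknown", init=False)

    @classmethod
    def from_profiles(
        cls,
        profiles: Mapping[str, StainProfile] | None = None,
        stage1_min_deficit: float = 10.0,
    ) -> "ClassificationRule":
        """Build interval bounds as midpoints between adjacent class deficits.

        The printed class profiles are the calibration anchors; for each band
        a class accepts deficits between the midpoints to its nearest lower
        and higher neighbouring class values (unbounded at the extremes).
        """
        profiles = dict(profiles or STAIN_PROFILES)
        centers = {name: p.deficit_rgb for name, p in profiles.items()}
        intervals: dict[str, list[tuple[float, float]]] = {
            name: [] for name in profiles
        }
        for b in range(3):
            values = sorted({p.deficit_rgb[b] for p in profiles.values()})
            for name, p in profiles.items():
                v = p.deficit_rgb[b]
                i = values.index(v)
                lo = -np.inf if i == 0 else (v + values[i - 1]) / 2.0
                hi = np.inf if i == len(values) - 1 else (v + values[i + 1]) / 2.0
                intervals[name].append((lo, hi))
        rule = cls(
            stage1_min_deficit=stage1_min_deficit,
            intervals={k: tuple(v) for k, v in intervals.items()},
            centers=centers,
        )
        rule.validate()
        return rule

    def validate(self) -> None:
        for name, center in self.centers.items():
            if name not in self.intervals:
                raise ConfigurationError(f"class {name!r} has no intervals")
            if len(self.intervals[name]) != 3:
                raise ConfigurationError(f"class {name!r} needs 3 band intervals")
            got = classify_object(BandDifferences(center), self)
            if got != name:
                raise ConfigurationError(
                    f"rule table is ambiguous: centre of {name!r} classifies "
                    f"as {got!r}"
                )


def classify_object(d: BandDifferences, rule: ClassificationRule) -> str:
    """Assign a class label to one object's band deficits."""
    arr = d.d
    if float(arr.min()) < rule.stage1_min_deficit:
        return rule.REJECT
    candidates = [
        name
        for name, iv in rule.intervals.items()
        if all(lo <= x <= hi for x, (lo, hi) in zip(arr, iv))
    ]
    if not candidates:
        return rule.UNKNOWN
    dists = {
        name: float(np.linalg.norm(arr - np.asarray(rule.centers[name])))
        for name in candidates
    }
    return min(sorted(dists), key=dists.get)


#: Rule built from the bundled class profiles (midpoint intervals, gate 10).
DEFAULT_RULE = ClassificationRule.from_profiles()


@dataclass(frozen=True)
class DifferenceSummary:
    """Per-class band-deficit statistics and the stained-class range."""

    table: pd.DataFrame  # index: class; columns: n, mean_R..sd_B
    overall_min: float  # min over stained-class per-band means
    overall_max: float


def summarize_differences(
    labeled: Sequence[tuple[str, BandDifferences]],
    min_n: int = 20,
    allow_fewer: bool = False,
    stained_classes: Sequence[str] = STAINED_CLASSES,
) -> DifferenceSummary:
    """Per-class mean +/- sd deficits and the overall stained range.

    At least ``min_n`` stained objects are required (the averaging floor of
    the analysis) unless ``allow_fewer`` is set.  The overall (min, max) runs
    over the per-band *class means* of the stained classes only.
    """
    n_stained = sum(1 for name, _ in labeled if name in stained_classes)
    if n_stained < min_n and not allow_fewer:
        raise SampleSizeError(
            f"only {n_stained} stained objects; {min_n} required "
            "(pass allow_fewer=True to override)"
        )
    by_class: dict[str, list[np.ndarray]] = {}
    for name, diff in labeled:
        by_class.setdefault(name, []).append(diff.d)
    rows = {}
    for name, ds in sorted(by_class.items()):
        arr = np.vstack(ds)
        mean = arr.mean(axis=0)
        sd = arr.std(axis=0)
        rows[name] = {
            "n": len(ds),
            **{f"mean_{b}": mean[i] for i, b in enumerate(BANDS)},
            **{f"sd_{b}": sd[i] for i, b in enumerate(BANDS)},
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    stained_means = [
        rows[name][f"mean_{b}"]
        for name in rows
        if name in stained_classes
        for b in BANDS
    ]
    if not stained_means:
        raise SampleSizeError("no stained-class objects to summarize")
    return DifferenceSummary(
        table=table,
        overall_min=float(min(stained_means)),
        overall_max=float(max(stained_means)),
    )


@dataclass(frozen=True)
class RelativeChange:
    """Per-band percent intensity change of a sample region vs a reference."""

    pct_rgb: tuple[float, float, float]

    @property
    def pct(self) -> np.ndarray:
        return np.asarray(self.pct_rgb, dtype=float)


def relative_change(
    reference_mean_rgb: Sequence[float], sample_mean_rgb: Sequence[float]
) -> RelativeChange:
    """``100 * (reference - sample) / reference`` per band.

    Positive when the sample is darker than the reference; when the
    reference is the background itself this equals ``100 * d / background``.
    """
    ref = np.asarray(reference_mean_rgb, dtype=float)
    sample = np.asarray(sample_mean_rgb, dtype=float)
    if np.any(ref <= 0):
        raise ConfigurationError("reference means must be positive")
    return RelativeChange(pct_rgb=tuple(100.0 * (ref - sample) / ref))


def mobile_relative_change(
    reference_image: "np.ndarray", sample_image: "np.ndarray"
) -> RelativeChange:
    """Per-band percent change between matched phone images of a conjugate pile.

    Identifies the complex area in each image (largest dark region under a
    global Otsu split) and compares its per-band mean against the undyed
    reference.  Stained piles show the largest change in the red band and
    essentially none in blue.
    """
    from .segmentation import largest_dark_region

    ref = largest_dark_region(reference_image)
    sample = largest_dark_region(sample_image)
    return relative_change(ref.mean_rgb, sample.mean_rgb)


@dataclass(frozen=True)
class TrendVerdict:
    monotone_bands: Mapping[Band, bool]
    is_monotone: bool
    is_flat: bool
    greatest_change_band: Band


def concentration_trend(
    series: Sequence[tuple[float, BandDifferences]]
) -> TrendVerdict:
    """Check that deficits fall (intensity rises) as the stain is diluted.

    ``series`` pairs each stain concentration with the measured class-mean
    deficits.  Ordered by decreasing concentration, deficits should strictly
    decrease in every band; the band with the largest total change is
    reported as the most concentration-sensitive channel.
    """
    if len(series) < 2:
        raise ConfigurationError("need at least two concentrations")
    ordered = sorted(series, key=lambda cd: -cd[0])
    mat = np.vstack([d.d for _, d in ordered])  # rows: decreasing conc
    diffs = np.diff(mat, axis=0)
    monotone = {b: bool((diffs[:, i] < 0).all()) for i, b in enumerate(BANDS)}
    total_change = np.abs(mat[0] - mat[-1])
    return TrendVerdict(
        monotone_bands=monotone,
        is_monotone=all(monotone.values()),
        is_flat=bool((diffs == 0).all()),
        greatest_change_band=BANDS[int(np.argmax(total_change))],
    )
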