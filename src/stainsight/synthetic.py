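"""Seedable synthetic bright-field scene generator with exact ground truth.

Emulates the visualization compartment of a magnetically driven staining chip:
a near-uniform bright background (mean intensity ~225 per 8-bit band), dark
4.5 µm superparamagnetic beads, unstained cells, and cells stained with the
four basic stains (trypan blue, safranin, methylene blue, crystal violet),
each characterised by a per-band intensity deficit relative to the background.

Objects are rendered as filled disks.  Each object carries a per-band
transmittance ``T_c = (background - deficit_c) / background``; the rendered
pixel value is the background field multiplied by the product of the
transmittances of every object covering that pixel.  For a single
non-overlapping disk this reproduces ``background - deficit`` exactly, while
overlapping objects in clustered placement darken multiplicatively, the way
stacked absorbing layers do in bright-field imaging.  Magnet-gathered
conjugate clusters are therefore darker than any single cell in one focal
plane, which is what a low-resolution phone rendering of the chip actually
shows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import disk as _disk
from skimage.transform import rescale

from .errors import ConfigurationError, PlacementError

Band = Literal["R", "G", "B"]
BANDS: tuple[Band, Band, Band] = ("R", "G", "B")

#: Default background mean, per band (8-bit intensity units).
BACKGROUND_MEAN = 225.0

#: Physical diameters in micrometres.
BEAD_DIAMETER_UM = 4.5
K562_DIAMETER_UM = 15.0
#: Patient lymphocytes are ~2.5x smaller than K562 cells.
LYMPHOCYTE_DIAMETER_UM = K562_DIAMETER_UM / 2.5


@dataclass(frozen=True)
class OpticsProfile:
    """Imaging geometry and noise of one acquisition modality.

    Parameters
    ----------
    background_mean_rgb : per-band mean of the empty field, 0-255.
    noise_sd : per-pixel Gaussian noise standard deviation (intensity units).
    blur_sigma : Gaussian blur applied after rendering, in pixels.
    pixel_scale : micrometres per pixel.
    image_shape : (rows, cols) of the rendered frame.
    modality : "microscope" or "phone".
    """

    background_mean_rgb: tuple[float, float, float] = (
        BACKGROUND_MEAN,
        BACKGROUND_MEAN,
        BACKGROUND_MEAN,
    )
    noise_sd: float = 3.0
    blur_sigma: float = 0.0
    pixel_scale: float = 1.625
    image_shape: tuple[int, int] = (768, 1024)
    modality: str = "microscope"
    name: str = "custom"

    def __post_init__(self) -> None:
        for v in self.background_mean_rgb:
            if not 0.0 <= v <= 255.0:
                raise ConfigurationError(
                    f"background mean {v} outside [0, 255]"
                )
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.pixel_scale <= 0:
            raise ConfigurationError("pixel_scale must be > 0")
        if self.blur_sigma < 0:
            raise ConfigurationError("blur_sigma must be >= 0")


# Objective presets assume a camera with a 6.5 um sensor pixel, giving the
# familiar scale ladder 1.625 / 0.65 / 0.325 / 0.13 um/px at 4x-50x.
MICROSCOPE_4X = OpticsProfile(pixel_scale=1.625, name="microscope_4x")
MICROSCOPE_10X = OpticsProfile(pixel_scale=0.65, name="microscope_10x")
MICROSCOPE_20X = OpticsProfile(pixel_scale=0.325, name="microscope_20x")
MICROSCOPE_50X = OpticsProfile(pixel_scale=0.13, name="microscope_50x")
#: A 12 MP phone held ~10 cm from the chip resolves far coarser than any
#: objective; 8 um/px with mild blur and slightly higher noise.
PHONE = OpticsProfile(
    pixel_scale=8.0,
    noise_sd=4.0,
    blur_sigma=1.0,
    image_shape=(156, 208),
    modality="phone",
    name="phone",
)

OPTICS_PRESETS: Mapping[str, OpticsProfile] = {
    p.name: p
    for p in (MICROSCOPE_4X, MICROSCOPE_10X, MICROSCOPE_20X, MICROSCOPE_50X, PHONE)
}

#: The quantitative focal-plane analysis operates at the 4x objective.
DEFAULT_OPTICS = MICROSCOPE_4X


@dataclass(frozen=True)
class StainProfile:
    """Named per-band intensity deficit relative to the background.

    ``deficit_rgb`` is the drop below the background mean in each band; the
    dominant band — the band of the dye's own hue — stays brightest, i.e. has
    the smallest deficit.
    """

    name: str
    deficit_rgb: tuple[float, float, float]
    dominant_band: Band | None = None

    def __post_init__(self) -> None:
        if any(d < 0 for d in self.deficit_rgb):
            raise ConfigurationError(f"negative deficit in profile {self.name!r}")
        if self.dominant_band is not None:
            i = BANDS.index(self.dominant_band)
            if self.deficit_rgb[i] > min(self.deficit_rgb):
                raise ConfigurationError(
                    f"dominant band {self.dominant_band} of {self.name!r} "
                    "is not a smallest-deficit band"
                )


# Bundled per-band deficits for each object class (8-bit intensity units),
# measured against a 225-mean background at high magnification.
BEAD = StainProfile("bead", (125.0, 120.0, 140.0))
UNSTAINED = StainProfile("unstained", (15.0, 15.0, 30.0))
TB = StainProfile("TB", (50.0, 40.0, 40.0), dominant_band="B")
SAFRANIN = StainProfile("safranin", (25.0, 135.0, 100.0), dominant_band="R")
MB = StainProfile("MB", (100.0, 100.0, 45.0), dominant_band="B")
CV = StainProfile("CV", (100.0, 115.0, 30.0), dominant_band="B")

STAIN_PROFILES: Mapping[str, StainProfile] = {
    p.name: p for p in (BEAD, UNSTAINED, TB, SAFRANIN, MB, CV)
}
#: Classes that correspond to a dye actually bound to a cell.
STAINED_CLASSES: tuple[str, ...] = ("TB", "safranin", "MB", "CV")
#: Classes rendered as cells (sized like cells, counted as cells).
CELL_CLASSES: tuple[str, ...] = ("unstained",) + STAINED_CLASSES


@dataclass(frozen=True)
class ObjectSpec:
    """One object to paint: its class, physical size and pixel position."""

    kind: str
    diameter_um: float
    center: tuple[float, float]
    cluster_id: int | None = None

    def __post_init__(self) -> None:
        if self.diameter_um <= 0:
            raise ConfigurationError("diameter_um must be > 0")

    def radius_px(self, pixel_scale: float) -> float:
        return self.diameter_um / (2.0 * pixel_scale)


def default_diameter(kind: str) -> float:
    """Default physical diameter (um) for a bundled object class."""
    return BEAD_DIAMETER_UM if kind == "bead" else K562_DIAMETER_UM


@dataclass(frozen=True)
class SceneSpec:
    """Declarative synthetic scene: optics, objects and a seed.

    Objects can be given explicitly (``objects``) or as counts per class
    (``counts``) placed automatically according to ``placement``:
    ``non_overlapping`` rejects overlapping draws, ``clustered`` gathers the
    objects into Gaussian clumps around a few cluster centres (the way the
    magnet piles conjugates up).
    """

    optics: OpticsProfile = DEFAULT_OPTICS
    objects: tuple[ObjectSpec, ...] = ()
    counts: Mapping[str, int] = field(default_factory=dict)
    placement: str = "non_overlapping"
    n_clusters: int = 1
    cluster_sigma_factor: float = 3.0
    diameter_overrides: Mapping[str, float] = field(default_factory=dict)
    stain_overrides: Mapping[str, StainProfile] = field(default_factory=dict)
    seed: int = 0

    def profile(self, kind: str) -> StainProfile:
        if kind in self.stain_overrides:
            return self.stain_overrides[kind]
        try:
            return STAIN_PROFILES[kind]
        except KeyError:
            raise ConfigurationError(f"unknown object class {kind!r}") from None

    def diameter(self, kind: str) -> float:
        return self.diameter_overrides.get(kind, default_diameter(kind))


@dataclass(frozen=True)
class ObjectRecord:
    """Ground-truth record for one painted object."""

    kind: str
    area_px: int
    center: tuple[float, float]
    deficit_rgb: tuple[float, float, float]
    cluster_id: int | None = None


@dataclass(frozen=True)
class GroundTruth:
    """Exact annotation of a rendered scene.

    ``total_conjugate_area_px`` is the pixel-union area of all painted
    objects (overlapping disks merge, as bead clusters do on the chip);
    for non-overlapping scenes it equals the sum of per-object areas.
    """

    objects: tuple[ObjectRecord, ...]
    counts: Mapping[str, int]
    total_conjugate_area_px: int
    mean_cell_area_px: float

    def count(self, kind: str | None = None) -> int:
        if kind is None:
            return len(self.objects)
        return self.counts.get(kind, 0)

    def to_dict(self) -> dict:
        return {
            "objects": [
                {
                    "kind": o.kind,
                    "area_px": o.area_px,
                    "center": list(o.center),
                    "deficit_rgb": list(o.deficit_rgb),
                    "cluster_id": o.cluster_id,
                }
                for o in self.objects
            ],
            "totals": {
                "counts": dict(self.counts),
                "total_conjugate_area_px": self.total_conjugate_area_px,
                "mean_cell_area_px": self.mean_cell_area_px,
            },
        }


# ---------------------------------------------------------------------------
# placement


def _place_non_overlapping(
    rng: np.random.Generator,
    radii: Sequence[float],
    shape: tuple[int, int],
    margin: float = 2.0,
    max_tries_per_object: int = 400,
) -> list[tuple[float, float]]:
    rows, cols = shape
    centers: list[tuple[float, float]] = []
    placed_r: list[float] = []
    for r in radii:
        lo_r, hi_r = r + 1.0, rows - r - 1.0
        lo_c, hi_c = r + 1.0, cols - r - 1.0
        if hi_r <= lo_r or hi_c <= lo_c:
            raise PlacementError(
                f"object radius {r:.1f}px does not fit the {shape} frame"
            )
        for _ in range(max_tries_per_object):
            cr = rng.uniform(lo_r, hi_r)
            cc = rng.uniform(lo_c, hi_c)
            ok = all(
                (cr - pr) ** 2 + (cc - pc) ** 2 >= (r + r2 + margin) ** 2
                for (pr, pc), r2 in zip(centers, placed_r)
            )
            if ok:
                centers.append((cr, cc))
                placed_r.append(r)
                break
        else:
            raise PlacementError(
                f"could not place object {len(centers) + 1}/{len(radii)} "
                f"without overlap: field too dense "
                f"({len(radii)} objects in {rows}x{cols}px)"
            )
    return centers


def _place_clustered(
    rng: np.random.Generator,
    radii: Sequence[float],
    shape: tuple[int, int],
    n_clusters: int,
    sigma_factor: float,
) -> tuple[list[tuple[float, float]], list[int]]:
    rows, cols = shape
    mean_r = float(np.mean(radii))
    sigma = sigma_factor * mean_r
    pad = 4.0 * sigma + mean_r
    centers_of_mass = [
        (
            rng.uniform(min(pad, rows / 2), max(rows - pad, rows / 2)),
            rng.uniform(min(pad, cols / 2), max(cols - pad, cols / 2)),
        )
        for _ in range(n_clusters)
    ]
    centers: list[tuple[float, float]] = []
    cluster_ids: list[int] = []
    for i, r in enumerate(radii):
        k = int(rng.integers(n_clusters))
        mr, mc = centers_of_mass[k]
        cr = float(np.clip(mr + rng.normal(0, sigma), r + 1, rows - r - 1))
        cc = float(np.clip(mc + rng.normal(0, sigma), r + 1, cols - r - 1))
        centers.append((cr, cc))
        cluster_ids.append(k)
    return centers, cluster_ids


def _resolve_objects(
    spec: SceneSpec, rng: np.random.Generator
) -> list[ObjectSpec]:
    if spec.objects and spec.counts:
        raise ConfigurationError("give either explicit objects or counts, not both")
    if spec.objects:
        rows, cols = spec.optics.image_shape
        for o in spec.objects:
            r, c = o.center
            if not (0 <= r < rows and 0 <= c < cols):
                raise ConfigurationError(f"object center {o.center} outside image")
        return list(spec.objects)

    kinds: list[str] = []
    for kind, n in spec.counts.items():
        spec.profile(kind)  # validates the class name
        kinds.extend([kind] * int(n))
    radii = [spec.diameter(k) / (2 * spec.optics.pixel_scale) for k in kinds]
    if not kinds:
        return []
    if spec.placement == "non_overlapping":
        centers = _place_non_overlapping(rng, radii, spec.optics.image_shape)
        cluster_ids: Sequence[int | None] = [None] * len(kinds)
    elif spec.placement == "clustered":
        centers, ids = _place_clustered(
            rng, radii, spec.optics.image_shape, spec.n_clusters,
            spec.cluster_sigma_factor,
        )
        cluster_ids = list(ids)
    else:
        raise ConfigurationError(f"unknown placement mode {spec.placement!r}")
    return [
        ObjectSpec(kind=k, diameter_um=spec.diameter(k), center=c, cluster_id=cid)
        for k, c, cid in zip(kinds, centers, cluster_ids)
    ]


# ---------------------------------------------------------------------------
# rendering


def render_scene(spec: SceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render a scene to an 8-bit RGB image and its exact ground truth.

    The same ``SceneSpec`` (including its seed) always produces a
    bit-identical image and annotation.
    """
    rng = np.random.default_rng(spec.seed)
    objects = _resolve_objects(spec, rng)
    rows, cols = spec.optics.image_shape
    bg = np.asarray(spec.optics.background_mean_rgb, dtype=float)

    field_ = np.broadcast_to(bg, (rows, cols, 3)).copy()
    if spec.optics.noise_sd > 0:
        field_ += rng.normal(0.0, spec.optics.noise_sd, size=(rows, cols, 3))

    # per-pixel transmittance product across objects
    transmittance = np.ones((rows, cols, 3), dtype=float)
    records: list[ObjectRecord] = []
    union = np.zeros((rows, cols), dtype=bool)
    for obj in objects:
        profile = spec.profile(obj.kind)
        r_px = obj.radius_px(spec.optics.pixel_scale)
        rr, cc = _disk(obj.center, r_px, shape=(rows, cols))
        t = (bg - np.asarray(profile.deficit_rgb)) / bg
        transmittance[rr, cc] *= t
        union[rr, cc] = True
        records.append(
            ObjectRecord(
                kind=obj.kind,
                area_px=int(rr.size),
                center=obj.center,
                deficit_rgb=profile.deficit_rgb,
                cluster_id=obj.cluster_id,
            )
        )
    field_ *= transmittance

    if spec.optics.blur_sigma > 0:
        field_ = gaussian_filter(
            field_, sigma=(spec.optics.blur_sigma, spec.optics.blur_sigma, 0)
        )

    image = np.clip(np.rint(field_), 0, 255).astype(np.uint8)

    counts: dict[str, int] = {}
    for rec in records:
        counts[rec.kind] = counts.get(rec.kind, 0) + 1
    cell_areas = [r.area_px for r in records if r.kind in CELL_CLASSES]
    gt = GroundTruth(
        objects=tuple(records),
        counts=counts,
        total_conjugate_area_px=int(union.sum()),
        mean_cell_area_px=float(np.mean(cell_areas)) if cell_areas else 0.0,
    )
    return image, gt


def render_phone_view(
    image: np.ndarray,
    source_optics: OpticsProfile,
    phone_optics: OpticsProfile = PHONE,
    seed: int = 0,
) -> np.ndarray:
    """Re-render a microscope-scale image at phone resolution.

    Downsamples by the pixel-scale ratio with anti-aliasing, applies the
    phone profile's blur, and adds its sensor noise.  Deterministic for a
    given seed.
    """
    if phone_optics.pixel_scale <= source_optics.pixel_scale:
        raise ConfigurationError(
            "phone pixel_scale must exceed the source pixel_scale "
            f"({phone_optics.pixel_scale} <= {source_optics.pixel_scale})"
        )
    factor = source_optics.pixel_scale / phone_optics.pixel_scale
    small = rescale(
        image.astype(float),
        factor,
        channel_axis=2,
        anti_aliasing=True,
        preserve_range=True,
    )
    if phone_optics.blur_sigma > 0:
        small = gaussian_filter(
            small, sigma=(phone_optics.blur_sigma, phone_optics.blur_sigma, 0)
        )
    if phone_optics.noise_sd > 0:
        rng = np.random.default_rng(seed)
        small = small + rng.normal(0.0, phone_optics.noise_sd, size=small.shape)
    return np.clip(np.rint(small), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# compartment-pair fixtures

#: Rendered first-compartment cell counts per density preset.  These are
#: scaled-down focal-plane equivalents chosen so every scene remains a
#: non-overlapping field; the ultra_low preset keeps the chip's ~95-cell
#: detection-floor regime at its true scale.
DENSITY_FIRST_COUNTS: Mapping[str, int] = {
    "high": 300,
    "medium": 200,
    "low": 120,
    "ultra_low": 95,
}


#: Conjugate-pile fixture: the magnet gathers conjugates into one dense pile
#: a few hundred micrometres across — the only structure a phone resolves.
MOBILE_PILE_COUNT = 300
MOBILE_PILE_SIGMA_FACTOR = 6.0


def make_mobile_pair(
    seed: int,
    stain: str = "TB",
    reference: str = "unstained",
    count: int = MOBILE_PILE_COUNT,
    sigma_factor: float = MOBILE_PILE_SIGMA_FACTOR,
    optics: OpticsProfile = DEFAULT_OPTICS,
    phone_optics: OpticsProfile = PHONE,
) -> tuple[np.ndarray, np.ndarray]:
    """Matched phone-resolution images of a conjugate pile, with/without dye.

    Renders the same magnet-gathered pile geometry twice — once with the
    reference (undyed) class and once with the stain — at microscope scale,
    then re-renders both at phone resolution.  Returns
    ``(reference_image, stained_image)``.
    """
    out = []
    for kind in (reference, stain):
        spec = SceneSpec(
            optics=optics,
            counts={kind: count},
            placement="clustered",
            n_clusters=1,
            cluster_sigma_factor=sigma_factor,
            seed=seed,
        )
        image, _ = render_scene(spec)
        out.append(render_phone_view(image, optics, phone_optics, seed=seed + 500))
    return out[0], out[1]


def make_compartment_pair(
    density: str,
    loss_fraction: float,
    seed: int,
    stain: str = "TB",
    optics: OpticsProfile = DEFAULT_OPTICS,
    first_count: int | None = None,
    bead_count: int = 0,
) -> tuple[SceneSpec, SceneSpec]:
    """Build matched first/last-compartment scene specs.

    The last compartment holds ``round(first * (1 - loss_fraction))`` cells —
    the conjugates lost in magnet transit — while bead content is preserved.
    """
    if not 0.0 <= loss_fraction < 1.0:
        raise ConfigurationError("loss_fraction must be in [0, 1)")
    if first_count is None:
        try:
            first_count = DENSITY_FIRST_COUNTS[density]
        except KeyError:
            raise ConfigurationError(f"unknown density preset {density!r}") from None
    last_count = int(round(first_count * (1.0 - loss_fraction)))
    first = SceneSpec(
        optics=optics,
        counts={stain: first_count, **({"bead": bead_count} if bead_count else {})},
        seed=seed,
    )
    last = replace(
        first,
        counts={stain: last_count, **({"bead": bead_count} if bead_count else {})},
        seed=seed + 1,
    )
    return first, last
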