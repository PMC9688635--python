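"""Shared fixtures: rendered scenes are expensive, so build them once."""

from __future__ import annotations

import numpy as np
import pytest

import stainsight as ss
from stainsight.segmentation import default_min_object_area
from stainsight.synthetic import CELL_CLASSES, STAIN_PROFILES

NOISELESS = ss.OpticsProfile(noise_sd=0.0, name="noiseless_4x")


@pytest.fixture(scope="session")
def noiseless_optics() -> ss.OpticsProfile:
    return NOISELESS


@pytest.fixture(scope="session")
def min_area() -> float:
    return default_min_object_area(NOISELESS.pixel_scale)


def render_class_scene(kind: str, n: int, seed: int, optics: ss.OpticsProfile):
    spec = ss.SceneSpec(optics=optics, counts={kind: n}, seed=seed)
    return ss.render_scene(spec)


def segment_scene(image: np.ndarray, min_object_area: float):
    bg = ss.estimate_background(image)
    objects = ss.segment_objects(image, bg, min_object_area=min_object_area)
    return bg, objects


@pytest.fixture(scope="session")
def noisy_class_recovery(min_area):
    """100 objects per class at default noise, run through the full
    segment + band-difference pipeline; keyed by class name."""
    out = {}
    for i, kind in enumerate(STAIN_PROFILES):
        image, gt = render_class_scene(kind, 100, seed=100 + i, optics=ss.DEFAULT_OPTICS)
        bg, objects = segment_scene(image, min_area)
        diffs = [ss.band_differences(o, bg) for o in objects]
        out[kind] = {
            "image": image,
            "gt": gt,
            "bg": bg,
            "objects": objects,
            "diffs": diffs,
            "mean_d": np.vstack([d.d for d in diffs]).mean(axis=0),
        }
    return out


@pytest.fixture(scope="session")
def noiseless_tb_scene(min_area):
    """20 disjoint TB-stained cells, no noise, no blur, with its pipeline run."""
    image, gt = render_class_scene("TB", 20, seed=1, optics=NOISELESS)
    bg, objects = segment_scene(image, min_area)
    return {"image": image, "gt": gt, "bg": bg, "objects": objects}


__all__ = ["CELL_CLASSES", "render_class_scene", "segment_scene"]
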