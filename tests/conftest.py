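"""Shared fixtures: small phantom geometries and a pipeline round-trip helper.

Most tests run on a miniature geometry (192x64 B-scans, 64-px crops, five
windows) that mirrors the structure of the nominal 1534x512 / 512-px layout
while keeping the suite fast; acceptance tests use the full geometry.
"""
from __future__ import annotations

import numpy as np
import pytest

from octlayers import (
    EvalConfig,
    PhantomSpec,
    boundaries_to_classmap,
    cut_crops,
    generate_phantom,
    specific_crop,
)
from octlayers.postproc import extract_boundaries, fuse_crops
from octlayers.segment import (
    OracleBackend,
    instances_to_labelmap,
    select_instances,
)

SMALL = dict(
    width=192,
    height=64,
    profile="retinal7",
    boundary_waviness=1.0,
    mean_layer_thicknesses=(6.0, 8.0, 7.0, 7.0, 5.0, 6.0),
    fovea_depth=16.0,
    fovea_width=40.0,
    speckle_level=0.2,
)
SMALL_CROP = 64


@pytest.fixture
def small_spec() -> PhantomSpec:
    return PhantomSpec(seed=11, **SMALL)


@pytest.fixture
def small_phantom(small_spec):
    bscan, bounds = generate_phantom(small_spec)
    labels = boundaries_to_classmap(bounds, small_spec.height)
    return bscan, bounds, labels


@pytest.fixture
def small_eval_config() -> EvalConfig:
    return EvalConfig.scaled(SMALL["width"])


def oracle_roundtrip(bscan, gt_labels, profile, crop_size, backend=None, convention="edge"):
    """Crop → segment → select → fuse → extract, returning (fused, boundaries)."""
    crops = specific_crop(gt_labels.shape[1], crop_size)
    if backend is None:
        backend = OracleBackend(profile, gt_labels)
    elif hasattr(backend, "set_ground_truth"):
        backend.set_ground_truth(gt_labels)
    label_maps = []
    for crop_img, window in zip(cut_crops(bscan.pixels, crops), crops.windows):
        selected, _ = select_instances(backend.segment(crop_img, window), profile)
        label_maps.append(instances_to_labelmap(selected, profile, crop_size))
    fused = fuse_crops(label_maps, crops)
    return fused, extract_boundaries(fused, profile, convention)
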