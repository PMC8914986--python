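"""Dataset I/O: specific-crop partitioning, COCO annotations, augmentation.

A full-width B-scan (nominally 1534x512 px) is partitioned into square crops
at fixed column offsets — successive multiples of half the crop size, with a
final offset clamped so the last crop is flush with the right edge.  For the
nominal geometry this yields crops at columns 0, 256, 512, 768 and 1022 with
50% overlap between neighbours.  Crops alternate between *main* windows
(whose columns compose the final fused image) and *auxiliary* windows (used
to repair incomplete segmentation at main-crop borders).

Annotations travel as COCO-style JSON: one category per layer region, one
instance per (image, region) with an uncompressed run-length encoded mask
(column-major counts, zero-run first), a bounding box and an area.  The RLE
round trip is exactly lossless at the binary-mask level.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import scipy.ndimage as ndi

from .phantom import BScan, BoundarySet, boundaries_to_classmap
from .profiles import PROFILES, get_profile

__all__ = [
    "CropWindow",
    "CropSet",
    "AnnotationRecord",
    "CropError",
    "specific_crop",
    "cut_crops",
    "rle_encode",
    "rle_decode",
    "write_coco",
    "read_coco",
    "rotate_augment",
    "save_bscan",
    "load_bscan",
    "save_labelmap",
    "load_labelmap",
]

MAIN = "main"
AUXILIARY = "auxiliary"


class CropError(ValueError):
    """Invalid crop geometry."""


@dataclass(frozen=True)
class CropWindow:
    """One square crop at a fixed column offset."""

    offset: int
    size: int
    role: str
    index: str  # ordinal letter; mains are lettered before auxiliaries

    def __post_init__(self) -> None:
        if self.offset < 0:
            raise CropError("crop offset must be non-negative")
        if self.role not in (MAIN, AUXILIARY):
            raise CropError(f"unknown crop role {self.role!r}")

    @property
    def stop(self) -> int:
        return self.offset + self.size

    @property
    def center(self) -> float:
        return self.offset + self.size / 2.0

    def covers(self, column: int) -> bool:
        return self.offset <= column < self.stop


@dataclass(frozen=True)
class CropSet:
    windows: tuple[CropWindow, ...]
    image_width: int

    def __post_init__(self) -> None:
        if not self.windows:
            raise CropError("empty crop set")
        offs = [w.offset for w in self.windows]
        if offs != sorted(offs) or len(set(offs)) != len(offs):
            raise CropError("crop offsets must be strictly increasing")
        if self.windows[-1].stop > self.image_width or offs[0] != 0:
            raise CropError("crops must lie inside [0, image_width)")
        # union of half-open windows must cover every column
        reach = 0
        for w in self.windows:
            if w.offset > reach:
                raise CropError(f"coverage gap before column {w.offset}")
            reach = max(reach, w.stop)
        if reach < self.image_width:
            raise CropError("crops do not reach the right edge")

    @property
    def size(self) -> int:
        return self.windows[0].size

    @property
    def mains(self) -> tuple[CropWindow, ...]:
        return tuple(w for w in self.windows if w.role == MAIN)

    @property
    def auxiliaries(self) -> tuple[CropWindow, ...]:
        return tuple(w for w in self.windows if w.role == AUXILIARY)


def specific_crop(image_width: int, crop_size: int = 512) -> CropSet:
    """Fixed-position overlapping crop layout covering the full width.

    Offsets are the successive multiples of ``crop_size // 2`` for which the
    crop still fits; if those stop short of the right edge a final crop is
    clamped to ``image_width - crop_size``.  Roles alternate main/auxiliary in
    offset order, starting with main.  For the nominal (1534, 512) geometry
    this reproduces offsets [0, 256, 512, 768, 1022] with roles
    [main, aux, main, aux, main].
    """
    if crop_size < 2:
        raise CropError("crop_size must be at least 2 px")
    if crop_size > image_width:
        raise CropError(
            f"crop_size {crop_size} exceeds image width {image_width}"
        )
    half = crop_size // 2
    offsets = []
    offset = 0
    while offset + crop_size <= image_width:
        offsets.append(offset)
        offset += half
    if offsets[-1] + crop_size < image_width:
        offsets.append(image_width - crop_size)

    n_mains = (len(offsets) + 1) // 2
    windows = []
    mains_seen = aux_seen = 0
    for i, off in enumerate(offsets):
        if i % 2 == 0:
            role, index = MAIN, chr(ord("A") + mains_seen)
            mains_seen += 1
        else:
            role, index = AUXILIARY, chr(ord("A") + n_mains + aux_seen)
            aux_seen += 1
        windows.append(CropWindow(offset=off, size=crop_size, role=role, index=index))
    return CropSet(windows=tuple(windows), image_width=image_width)


def cut_crops(grid: np.ndarray, crops: CropSet) -> list[np.ndarray]:
    """Slice a (height, width) grid into crop-sized sub-grids (no resampling).

    Each output covers rows ``[0, size)`` and columns ``[offset, offset+size)``
    of the source; images and label maps cut with the same windows therefore
    stay pixel-aligned.
    """
    grid = np.asarray(grid)
    if grid.ndim != 2:
        raise CropError("expected a 2-D grid")
    if grid.shape[1] != crops.image_width:
        raise CropError(
            f"grid width {grid.shape[1]} does not match crop set width "
            f"{crops.image_width}"
        )
    if grid.shape[0] < crops.size:
        raise CropError("grid height is smaller than the crop size")
    return [grid[: crops.size, w.offset : w.stop].copy() for w in crops.windows]


# ---------------------------------------------------------------------------
# COCO-style annotation I/O


def rle_encode(mask: np.ndarray) -> dict:
    """Uncompressed COCO run-length encoding (column-major, zero-run first)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    flat = mask.flatten(order="F")
    if flat.size == 0:
        return {"size": list(mask.shape), "counts": []}
    breaks = np.flatnonzero(flat[1:] != flat[:-1]) + 1
    runs = np.diff(np.concatenate(([0], breaks, [flat.size])))
    counts = runs.tolist()
    if flat[0]:
        counts = [0] + counts
    return {"size": [int(mask.shape[0]), int(mask.shape[1])], "counts": counts}


def rle_decode(rle: dict) -> np.ndarray:
    """Decode an uncompressed RLE dict back to a boolean mask."""
    h, w = (int(v) for v in rle["size"])
    counts = np.asarray(rle["counts"], dtype=np.int64)
    if counts.sum() != h * w:
        raise ValueError("RLE counts do not sum to the mask size")
    values = np.arange(counts.size) % 2 == 1
    flat = np.repeat(values, counts)
    return flat.reshape((h, w), order="F")


@dataclass
class AnnotationRecord:
    """Per-image annotation: a list of (category name, binary mask) instances."""

    image_id: int
    file_name: str
    width: int
    height: int
    profile: str
    instances: list[tuple[str, np.ndarray]]


def _tight_bbox_xywh(mask: np.ndarray) -> list[float]:
    rows, cols = np.nonzero(mask)
    return [
        float(cols.min()),
        float(rows.min()),
        float(cols.max() - cols.min() + 1),
        float(rows.max() - rows.min() + 1),
    ]


def write_coco(
    images: Sequence[BScan | np.ndarray],
    boundary_sets: Sequence[BoundarySet],
    path,
    file_names: Sequence[str] | None = None,
) -> Path:
    """Write COCO-style JSON annotations for a set of annotated B-scans.

    One instance is emitted per non-empty layer region of each image; regions
    with zero thickness everywhere produce no instance.  All boundary sets
    must share one profile.
    """
    if len(images) != len(boundary_sets):
        raise ValueError("one boundary set per image is required")
    profiles = {b.profile for b in boundary_sets}
    if len(profiles) > 1:
        raise ValueError(f"mixed profiles in one annotation file: {profiles}")
    profile = get_profile(boundary_sets[0].profile)

    coco: dict = {
        "info": {"description": f"octlayers annotations ({profile.name})"},
        "images": [],
        "annotations": [],
        "categories": [
            {"id": k + 1, "name": name, "supercategory": "layer"}
            for k, name in enumerate(profile.layer_names)
        ],
    }
    ann_id = 1
    for img_idx, (image, bset) in enumerate(zip(images, boundary_sets)):
        pixels = image.pixels if isinstance(image, BScan) else np.asarray(image)
        height, width = pixels.shape
        if width != bset.width:
            raise ValueError(f"image {img_idx}: width mismatch with boundaries")
        fname = (
            file_names[img_idx] if file_names is not None else f"image_{img_idx:04d}.png"
        )
        coco["images"].append(
            {"id": img_idx, "file_name": fname, "width": width, "height": height}
        )
        labels = boundaries_to_classmap(bset, height)
        for k in range(profile.n_layers):
            mask = labels == k + 1
            if not mask.any():
                continue
            coco["annotations"].append(
                {
                    "id": ann_id,
                    "image_id": img_idx,
                    "category_id": k + 1,
                    "segmentation": rle_encode(mask),
                    "area": int(mask.sum()),
                    "bbox": _tight_bbox_xywh(mask),
                    "iscrowd": 0,
                }
            )
            ann_id += 1
    path = Path(path)
    path.write_text(json.dumps(coco))
    return path


def read_coco(path) -> list[AnnotationRecord]:
    """Read COCO-style annotations back into per-image records.

    Category names must all belong to one known profile roster; anything else
    is rejected.
    """
    data = json.loads(Path(path).read_text())
    categories = {c["id"]: c["name"] for c in data.get("categories", [])}
    names = set(categories.values())
    profile = next(
        (p for p in PROFILES.values() if names <= set(p.layer_names)), None
    )
    if profile is None:
        raise ValueError(
            f"unknown category names {sorted(names)}; no profile roster matches"
        )
    records: dict[int, AnnotationRecord] = {}
    for im in data["images"]:
        records[im["id"]] = AnnotationRecord(
            image_id=im["id"],
            file_name=im.get("file_name", ""),
            width=im["width"],
            height=im["height"],
            profile=profile.name,
            instances=[],
        )
    for ann in data["annotations"]:
        name = categories.get(ann["category_id"])
        if name is None:
            raise ValueError(f"annotation references unknown category {ann['category_id']}")
        rec = records[ann["image_id"]]
        mask = rle_decode(ann["segmentation"])
        if mask.shape != (rec.height, rec.width):
            raise ValueError("mask size disagrees with its image record")
        rec.instances.append((name, mask))
    return [records[k] for k in sorted(records)]


# ---------------------------------------------------------------------------
# Rotation augmentation


def _rotate_labels_distance(labels: np.ndarray, angle: float) -> np.ndarray:
    """Rotate a label map by interpolating per-class signed distance fields.

    Each class (including background) is turned into a signed Euclidean
    distance field (negative inside), the fields are rotated with bilinear
    interpolation, and each output pixel takes the class whose field is most
    negative.  Boundaries are preserved to sub-pixel accuracy and the output
    remains a partition.
    """
    n_classes = int(labels.max()) + 1
    scores = np.empty((n_classes,) + labels.shape)
    for k in range(n_classes):
        mask = labels == k
        if mask.any():
            field = ndi.distance_transform_edt(~mask) - ndi.distance_transform_edt(mask)
        else:
            field = np.full(labels.shape, 1e6)
        # pixels rotated in from outside the frame belong to the background
        cval = -1e6 if k == 0 else 1e6
        scores[k] = ndi.rotate(
            field, angle, reshape=False, order=1, mode="constant", cval=cval
        )
    return np.argmin(scores, axis=0).astype(labels.dtype)


def rotate_augment(
    image: np.ndarray | BScan,
    annotation: BoundarySet | np.ndarray,
    angle: float | None = None,
    *,
    seed: int | None = None,
    max_angle: float = 10.0,
    mask_method: str = "nearest",
) -> tuple[np.ndarray, np.ndarray]:
    """Rotate an image and its layer annotation about the image centre.

    ``annotation`` may be a :class:`BoundarySet` (rasterized internally) or an
    existing label map; the rotated annotation is always returned as a label
    map, since boundary traces are not closed under rotation near steep
    boundaries.  ``angle`` is in degrees and limited to ±``max_angle`` (the
    training augmentation range); ``angle=None`` draws uniformly from that
    range using ``seed``.  Intensities are interpolated bilinearly; masks with
    nearest-neighbour lookup by default, or via signed-distance interpolation
    (``mask_method="distance"``) when sub-pixel boundary fidelity matters.
    Content that rotates out of the frame is filled with background and is
    irrecoverably lost — a round trip (+a then −a) is only an identity away
    from the frame edges.
    """
    pixels = image.pixels if isinstance(image, BScan) else np.asarray(image, dtype=float)
    if angle is None:
        angle = float(np.random.default_rng(seed).uniform(-max_angle, max_angle))
    if abs(angle) > max_angle:
        raise ValueError(f"|angle| must be <= {max_angle} degrees, got {angle}")
    if isinstance(annotation, BoundarySet):
        labels = boundaries_to_classmap(annotation, pixels.shape[0])
    else:
        labels = np.asarray(annotation)
        if labels.shape != pixels.shape:
            raise ValueError("label map shape must match the image")

    if angle == 0.0:
        return pixels.copy(), labels.copy()

    rotated_image = ndi.rotate(
        pixels, angle, reshape=False, order=1, mode="constant", cval=0.0
    )
    if mask_method == "distance":
        rotated_labels = _rotate_labels_distance(labels, angle)
    elif mask_method == "nearest":
        rotated_labels = ndi.rotate(
            labels, angle, reshape=False, order=0, mode="constant", cval=0
        )
    else:
        raise ValueError(f"unknown mask_method {mask_method!r}")
    return rotated_image, rotated_labels


# ---------------------------------------------------------------------------
# Image file helpers


def save_bscan(image: BScan | np.ndarray, path) -> Path:
    """Save a [0, 1] grayscale image as 8-bit PNG/TIFF."""
    pixels = image.pixels if isinstance(image, BScan) else np.asarray(image, dtype=float)
    path = Path(path)
    iio.imwrite(path, np.round(np.clip(pixels, 0, 1) * 255).astype(np.uint8))
    return path


def load_bscan(path) -> BScan:
    """Load an 8/16-bit grayscale image into a [0, 1] B-scan."""
    raw = iio.imread(path)
    if raw.ndim == 3:  # collapse any redundant colour channels
        raw = raw[..., 0]
    scale = 65535.0 if raw.dtype == np.uint16 else 255.0
    return BScan(pixels=raw.astype(float) / scale, provenance=str(path))


def save_labelmap(labels: np.ndarray, path) -> Path:
    """Save an integer label map as an 8-bit indexed PNG."""
    labels = np.asarray(labels)
    if labels.max() > 255:
        raise ValueError("label map has more than 255 classes")
    path = Path(path)
    iio.imwrite(path, labels.astype(np.uint8))
    return path


def load_labelmap(path) -> np.ndarray:
    raw = iio.imread(path)
    if raw.ndim == 3:
        raw = raw[..., 0]
    return raw.astype(np.int32)
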