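"""Bounding-box ratio statistics and anchor configuration.

Region-proposal networks detect objects through anchor boxes of preset
width/height ratios and pixel scales.  Retinal layers are extremely wide and
flat, so the stock anchor settings of a Mask R-CNN (ratios near 1) miss them;
the appropriate ratios are derived from the bounding-box ratio statistics of
the annotated layers themselves.  This module computes those statistics
(per-layer width/height histograms over instance bounding boxes) and emits
anchor configurations: preset configurations matching the published study
(retinal: ratios 16/32/64/128 with scales 8–128; retina+choroid: ratios
2/4/6/8/10), or a quantile-coverage heuristic for new data.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dataio import AnnotationRecord
from .profiles import get_profile

__all__ = [
    "RatioHistogram",
    "AnchorConfig",
    "bbox_ratio",
    "ratio_histogram",
    "propose_anchor_config",
    "RETINAL7_ANCHORS",
    "CHOROID3_ANCHORS",
]


@dataclass(frozen=True)
class AnchorConfig:
    """Anchor width/height ratios and pixel scales for a region proposal head."""

    ratios: tuple[float, ...]
    scales: tuple[float, ...]
    rois_per_image: int = 200

    def __post_init__(self) -> None:
        for name, values in (("ratios", self.ratios), ("scales", self.scales)):
            if not values:
                raise ValueError(f"{name} must be non-empty")
            if any(v <= 0 for v in values):
                raise ValueError(f"{name} must be positive")
            if list(values) != sorted(set(values)):
                raise ValueError(f"{name} must be strictly increasing")
        if self.rois_per_image <= 0:
            raise ValueError("rois_per_image must be positive")

    def to_json(self, path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps(
                {
                    "ratios": list(self.ratios),
                    "scales": list(self.scales),
                    "rois_per_image": self.rois_per_image,
                }
            )
        )
        return path

    @classmethod
    def from_json(cls, path) -> "AnchorConfig":
        d = json.loads(Path(path).read_text())
        return cls(
            ratios=tuple(d["ratios"]),
            scales=tuple(d["scales"]),
            rois_per_image=int(d.get("rois_per_image", 200)),
        )


#: Preset configurations for the two study profiles.
RETINAL7_ANCHORS = AnchorConfig(
    ratios=(16.0, 32.0, 64.0, 128.0), scales=(8.0, 16.0, 32.0, 64.0, 128.0)
)
CHOROID3_ANCHORS = AnchorConfig(
    ratios=(2.0, 4.0, 6.0, 8.0, 10.0), scales=(8.0, 16.0, 32.0, 64.0, 128.0)
)
_PRESETS = {"retinal7": RETINAL7_ANCHORS, "choroid3": CHOROID3_ANCHORS}


def bbox_ratio(mask: np.ndarray) -> float:
    """Width/height ratio of the tight bounding box of a binary mask.

    The box covers the maximum horizontal and vertical extents of the
    foreground, so the ratio depends only on those extents, not on the shape
    inside the box.
    """
    mask = np.asarray(mask, dtype=bool)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("cannot compute a bounding-box ratio of an empty mask")
    width = cols.max() - cols.min() + 1
    height = rows.max() - rows.min() + 1
    return float(width) / float(height)


@dataclass
class RatioHistogram:
    """Per-layer-class histograms of bounding-box ratios.

    ``per_class`` maps a layer name to ``(bin_centers, counts)``; bins are
    shared across classes and aligned to multiples of ``bin_width``.
    """

    per_class: dict[str, tuple[np.ndarray, np.ndarray]]
    bin_width: float

    def total_count(self) -> int:
        return int(sum(c.sum() for _, c in self.per_class.values()))

    def weighted_quantile(self, q: float) -> float:
        """Quantile of the pooled ratio distribution, using bin centers."""
        centers = np.concatenate([c for c, _ in self.per_class.values()])
        counts = np.concatenate([n for _, n in self.per_class.values()])
        order = np.argsort(centers)
        centers, counts = centers[order], counts[order].astype(float)
        if counts.sum() == 0:
            raise ValueError("empty histogram")
        cum = np.cumsum(counts) / counts.sum()
        return float(centers[np.searchsorted(cum, q, side="left").clip(0, len(centers) - 1)])

    def modes(self) -> dict[str, float]:
        """Bin center with the highest count, per class."""
        return {
            name: float(centers[np.argmax(counts)])
            for name, (centers, counts) in self.per_class.items()
            if counts.sum() > 0
        }

    def to_csv(self, path) -> Path:
        rows = [
            {"layer": name, "bin_center": float(c), "count": int(n)}
            for name, (centers, counts) in self.per_class.items()
            for c, n in zip(centers, counts)
        ]
        path = Path(path)
        pd.DataFrame(rows).to_csv(path, index=False)
        return path


def _iter_instances(
    annotations: Iterable,
) -> Iterable[tuple[str, np.ndarray]]:
    for item in annotations:
        if isinstance(item, AnnotationRecord):
            yield from item.instances
        else:
            yield item  # (name, mask) pair


def ratio_histogram(annotations: Iterable, bin_width: float = 1.0) -> RatioHistogram:
    """Histogram the bounding-box ratios of every instance, per layer class.

    ``annotations`` is an iterable of :class:`~octlayers.dataio.AnnotationRecord`
    or of ``(layer_name, mask)`` pairs.  The histogram total per class equals
    the number of instances of that class (counts are conserved).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    ratios: dict[str, list[float]] = {}
    for name, mask in _iter_instances(annotations):
        ratios.setdefault(name, []).append(bbox_ratio(mask))
    if not ratios:
        raise ValueError("no instances to histogram")
    all_vals = np.concatenate([np.asarray(v) for v in ratios.values()])
    lo = np.floor(all_vals.min() / bin_width) * bin_width
    hi = np.ceil(all_vals.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    centers = edges[:-1] + bin_width / 2
    per_class = {}
    for name, vals in ratios.items():
        counts, _ = np.histogram(vals, bins=edges)
        per_class[name] = (centers.copy(), counts)
    return RatioHistogram(per_class=per_class, bin_width=float(bin_width))


def propose_anchor_config(
    hist: RatioHistogram | None = None,
    crop_size: int = 512,
    profile: str | None = None,
) -> AnchorConfig:
    """Propose anchor ratios and scales for a dataset.

    With ``profile`` set, the study's preset configuration for that profile is
    returned verbatim.  Otherwise a documented heuristic covers the central
    mass of the ratio histogram: ratios are a doubling chain from the largest
    power of two at or below the 5th percentile up past the 95th percentile
    (so the histogram mode is always bracketed), and scales are powers of two
    from 8 px up to a quarter of the crop size.
    """
    if profile is not None:
        return _PRESETS[get_profile(profile).name]
    if hist is None:
        raise ValueError("either a histogram or a profile preset is required")
    if hist.total_count() == 0:
        raise ValueError("cannot propose anchors from an empty histogram")
    q_lo = max(hist.weighted_quantile(0.05), 1.0)
    q_hi = max(hist.weighted_quantile(0.95), q_lo)
    r = 2.0 ** np.floor(np.log2(q_lo))
    ratios = [r]
    while ratios[-1] < q_hi:
        ratios.append(ratios[-1] * 2.0)
    if len(ratios) < 2:
        ratios.append(ratios[-1] * 2.0)
    scales = []
    s = 8.0
    while s <= crop_size / 4 or not scales:
        scales.append(s)
        s *= 2.0
    return AnchorConfig(ratios=tuple(ratios), scales=tuple(scales))
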