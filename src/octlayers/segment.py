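"""Instance-segmentation backend contract, oracle backends, instance selection.

The pipeline treats the segmenter as a pluggable backend honouring one
contract: given a crop (and its window), return an :class:`InstanceSet` of
per-layer detections, each with a class name from the active profile roster,
a confidence score and a binary mask inside the crop.  Two reference backends
are provided:

* :class:`OracleBackend` — returns the rasterized ground truth, one instance
  per non-empty layer with score 1.0.  Used to validate the crop/fuse/extract
  plumbing end-to-end (the downstream pipeline must reproduce the ground
  truth exactly).
* :class:`PerturbedOracleBackend` — degrades the oracle in controlled ways
  (vertical shift, mask dilation, class drop-out, wrong-position duplicates)
  to exercise the selection rule and the evaluation metrics.

A trained neural instance segmenter (e.g. a Mask R-CNN) can be plugged in as
any object exposing the same ``segment(crop_image, window)`` method.

:func:`select_instances` implements the anatomical instance-selection rule:
when a class is detected more than once, keep the candidate whose vertical
position is consistent with the top-to-bottom layer ordering, breaking ties
by score and then by area.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Protocol, runtime_checkable

import numpy as np
import scipy.ndimage as ndi

from .dataio import CropSet, CropWindow
from .profiles import Profile, get_profile

__all__ = [
    "Instance",
    "InstanceSet",
    "PerturbationSpec",
    "SegmentationBackend",
    "OracleBackend",
    "PerturbedOracleBackend",
    "select_instances",
    "instances_to_labelmap",
]


@dataclass(frozen=True)
class Instance:
    """A single detected layer instance inside one crop."""

    class_name: str
    score: float
    mask: np.ndarray

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", mask)
        if mask.ndim != 2 or not mask.any():
            raise ValueError("instance mask must be a non-empty 2-D binary grid")
        if not np.isfinite(self.score) or not 0.0 <= self.score <= 1.0:
            raise ValueError("score must be a finite value in [0, 1]")

    @property
    def bbox(self) -> tuple[int, int, int, int]:
        """Tight (min_row, min_col, max_row, max_col) box of the mask."""
        rows, cols = np.nonzero(self.mask)
        return (int(rows.min()), int(cols.min()), int(rows.max()), int(cols.max()))

    @property
    def area(self) -> int:
        return int(self.mask.sum())

    @property
    def mean_row(self) -> float:
        rows = np.nonzero(self.mask)[0]
        return float(rows.mean())


@dataclass(frozen=True)
class InstanceSet:
    """Detections for one crop, truncated to a maximum count by score."""

    instances: tuple[Instance, ...]
    crop: CropWindow | None = None

    @classmethod
    def create(
        cls,
        instances,
        crop: CropWindow | None = None,
        max_instances: int = 200,
    ) -> "InstanceSet":
        instances = tuple(instances)
        if len(instances) > max_instances:
            # score-ranked truncation, stable for equal scores
            order = sorted(
                range(len(instances)), key=lambda i: (-instances[i].score, i)
            )[:max_instances]
            instances = tuple(instances[i] for i in sorted(order))
        return cls(instances=instances, crop=crop)

    def by_class(self, class_name: str) -> tuple[Instance, ...]:
        return tuple(i for i in self.instances if i.class_name == class_name)

    def __len__(self) -> int:
        return len(self.instances)


@runtime_checkable
class SegmentationBackend(Protocol):
    """Contract implemented by every segmentation backend."""

    def segment(self, crop_image: np.ndarray, window: CropWindow) -> InstanceSet:
        ...


@dataclass(frozen=True)
class PerturbationSpec:
    """Controlled degradations applied by the perturbed oracle.

    ``vertical_shift`` moves every mask down by that many rows (clipped at
    the crop edge); ``dilation`` grows every mask with a square structuring
    element of that radius; ``drop_prob`` removes instances at random (a
    scalar, or a per-class mapping); ``duplicate_prob`` adds a copy of an
    instance at an anatomically wrong position near the top of the crop.
    """

    vertical_shift: int = 0
    dilation: int = 0
    drop_prob: float | Mapping[str, float] = 0.0
    duplicate_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        probs = (
            list(self.drop_prob.values())
            if isinstance(self.drop_prob, Mapping)
            else [self.drop_prob]
        )
        probs.append(self.duplicate_prob)
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.dilation < 0:
            raise ValueError("dilation must be non-negative")

    def class_drop_prob(self, name: str) -> float:
        if isinstance(self.drop_prob, Mapping):
            return float(self.drop_prob.get(name, 0.0))
        return float(self.drop_prob)


def _shift_rows(mask: np.ndarray, shift: int) -> np.ndarray:
    """Shift a mask down (positive) or up (negative), clipping at the edges."""
    if shift == 0:
        return mask.copy()
    out = np.zeros_like(mask)
    if shift > 0:
        out[shift:] = mask[:-shift]
    else:
        out[:shift] = mask[-shift:]
    return out


class OracleBackend:
    """Ground-truth-backed segmentation oracle.

    Holds the full-image ground-truth label map and, for each crop window,
    returns one instance per layer present in the crop with the exact
    rasterized mask and score 1.0.
    """

    def __init__(
        self,
        profile: str | Profile,
        ground_truth: np.ndarray | None = None,
        max_instances: int = 200,
        score_threshold: float = 0.5,
    ) -> None:
        self.profile = get_profile(profile)
        self.max_instances = max_instances
        self.score_threshold = score_threshold
        self._ground_truth: np.ndarray | None = None
        if ground_truth is not None:
            self.set_ground_truth(ground_truth)

    def set_ground_truth(self, labels: np.ndarray) -> None:
        labels = np.asarray(labels)
        if labels.ndim != 2:
            raise ValueError("ground truth must be a 2-D label map")
        self._ground_truth = labels

    def _gt_crop(self, window: CropWindow) -> np.ndarray:
        if self._ground_truth is None:
            raise RuntimeError("oracle backend has no ground truth bound")
        return self._ground_truth[: window.size, window.offset : window.stop]

    def segment(self, crop_image: np.ndarray | None, window: CropWindow) -> InstanceSet:
        gt = self._gt_crop(window)
        instances = []
        for k, name in enumerate(self.profile.layer_names):
            mask = gt == k + 1
            if mask.any():
                instances.append(Instance(class_name=name, score=1.0, mask=mask))
        return InstanceSet.create(instances, crop=window, max_instances=self.max_instances)


class PerturbedOracleBackend(OracleBackend):
    """Oracle degraded according to a :class:`PerturbationSpec`.

    Deterministic given the perturbation seed and the crop offset (each crop
    gets its own derived random stream), so repeated runs are bit-identical.
    Scores reflect the perturbation strength so score-based tie-breaks stay
    exercisable; duplicates carry a reduced score.
    """

    def __init__(
        self,
        profile: str | Profile,
        perturbation: PerturbationSpec,
        ground_truth: np.ndarray | None = None,
        max_instances: int = 200,
        score_threshold: float = 0.5,
    ) -> None:
        super().__init__(profile, ground_truth, max_instances, score_threshold)
        self.perturbation = perturbation

    def segment(self, crop_image: np.ndarray | None, window: CropWindow) -> InstanceSet:
        base = super().segment(crop_image, window)
        p = self.perturbation
        rng = np.random.default_rng([p.seed, window.offset])
        penalty = 0.05 * (abs(p.vertical_shift) + p.dilation)
        score = float(np.clip(1.0 - penalty, 0.05, 1.0))
        out: list[Instance] = []
        for inst in base.instances:
            if rng.uniform() < p.class_drop_prob(inst.class_name):
                continue
            mask = inst.mask
            if p.dilation > 0:
                mask = ndi.binary_dilation(
                    mask, structure=np.ones((3, 3), dtype=bool), iterations=p.dilation
                )
            if p.vertical_shift != 0:
                mask = _shift_rows(mask, p.vertical_shift)
            if not mask.any():
                continue
            out.append(Instance(class_name=inst.class_name, score=score, mask=mask))
            if rng.uniform() < p.duplicate_prob:
                # misplaced copy hoisted to the top of the crop: violates the
                # anatomical ordering for every class below the first
                lift = inst.bbox[0] - 1
                dup = _shift_rows(inst.mask, -lift) if lift > 0 else inst.mask.copy()
                if dup.any():
                    out.append(
                        Instance(class_name=inst.class_name, score=0.6 * score, mask=dup)
                    )
        return InstanceSet.create(out, crop=window, max_instances=self.max_instances)


def select_instances(
    instance_set: InstanceSet, profile: str | Profile
) -> tuple[InstanceSet, tuple[str, ...]]:
    """Keep one instance per class, preferring anatomically ordered candidates.

    Classes are visited top-to-bottom.  A candidate is ordering-consistent if
    its mean foreground row does not lie above the mean row of the previously
    selected class; among candidates, consistency wins, then higher score,
    then larger area.  Classes with no candidate are reported as missing
    (data, not an error).  The operation is idempotent and returns at most one
    instance per class.
    """
    p = get_profile(profile)
    selected: list[Instance] = []
    missing: list[str] = []
    prev_row = -np.inf
    for name in p.layer_names:
        candidates = instance_set.by_class(name)
        if not candidates:
            missing.append(name)
            continue
        best = max(
            candidates,
            key=lambda i: (i.mean_row >= prev_row - 1e-9, i.score, i.area),
        )
        selected.append(best)
        if best.mean_row >= prev_row - 1e-9:
            prev_row = best.mean_row
    return (
        InstanceSet.create(selected, crop=instance_set.crop),
        tuple(missing),
    )


def instances_to_labelmap(
    instance_set: InstanceSet, profile: str | Profile, size: int | tuple[int, int]
) -> np.ndarray:
    """Paint instances into a per-pixel label map in roster (top-down) order.

    Later (deeper) classes overwrite earlier ones where masks overlap, which
    keeps each column's runs contiguous under vertical perturbations.
    """
    p = get_profile(profile)
    shape = (size, size) if isinstance(size, int) else tuple(size)
    labels = np.zeros(shape, dtype=np.int32)
    for k, name in enumerate(p.layer_names):
        for inst in instance_set.by_class(name):
            if inst.mask.shape != shape:
                raise ValueError("instance mask shape does not match the crop size")
            labels[inst.mask] = k + 1
    return labels
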