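"""Synthetic layered B-scan phantoms with known boundary geometry.

The generator produces grayscale OCT-like B-scans together with their exact
ground-truth boundary traces.  Each phantom consists of smooth, anatomically
ordered layer boundaries (low-frequency undulation plus a global curvature),
a central foveal pit where the inner retinal regions thin — and the innermost
ones vanish entirely, reproducing the layer drop-out seen at the fovea in real
scans — per-region intensity contrast, and multiplicative gamma-distributed
speckle.  It makes no attempt at physical OCT optics, vessel shadows or
pathology; it emulates the *geometry* a layer segmentation pipeline must
handle, not the physics of the instrument.

Coordinate convention: row 0 is the top of the image, column 0 the left;
boundary traces are real-valued row positions sampled once per column.  A
pixel row ``r`` belongs to region ``k`` iff ``snap(t_k) <= r < snap(t_{k+1})``
where ``snap`` rounds a trace to the nearest pixel row (ties upward).  With
this convention integer-valued traces rasterize exactly half-open
(``t_k <= r < t_{k+1}``) and real-valued traces stay within half a pixel of
the mask edge they produce.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .profiles import Profile, get_profile

__all__ = [
    "PhantomSpec",
    "BoundarySet",
    "BScan",
    "PhantomGeometryError",
    "BoundaryOrderError",
    "generate_phantom",
    "boundaries_to_classmap",
    "snap_traces",
    "write_boundaries_csv",
    "read_boundaries_csv",
]


class PhantomGeometryError(ValueError):
    """Requested phantom geometry cannot fit in the image."""


class BoundaryOrderError(ValueError):
    """Boundary traces violate the top-to-bottom anatomical ordering."""


# Per-profile study conditions: mean region thicknesses (px), foveal pit
# depth/width (px) and the fraction of the pit carried by each region (inner
# regions thin, outer ones keep their thickness).
_DEFAULTS: dict[str, dict] = {
    "retinal7": dict(
        thicknesses=(35.0, 55.0, 45.0, 50.0, 28.0, 38.0),
        fovea_depth=120.0,
        fovea_width=180.0,
        pit_weights=(0.35, 0.30, 0.20, 0.15, 0.0, 0.0),
    ),
    "choroid3": dict(
        thicknesses=(250.0, 120.0),
        fovea_depth=60.0,
        fovea_width=200.0,
        pit_weights=(1.0, 0.0),
    ),
}

# Mean reflectance per region, chosen so adjacent regions (and the background)
# differ by at least 0.1 before speckle.
_INTENSITIES: dict[str, tuple[float, ...]] = {
    "retinal7": (0.55, 0.30, 0.45, 0.26, 0.48, 0.80),
    "choroid3": (0.62, 0.35),
}
_BACKGROUND_INTENSITY = 0.08


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic B-scan.

    ``fovea_depth``, ``fovea_width`` and ``mean_layer_thicknesses`` default to
    per-profile values when left as ``None`` (see :func:`generate_phantom`).
    ``integer_traces`` rounds every boundary trace to whole pixel rows, which
    makes the rasterize→extract round trip exact rather than half-pixel
    accurate.
    """

    width: int = 1534
    height: int = 512
    profile: str = "retinal7"
    seed: int = 0
    speckle_level: float = 0.25
    fovea_depth: float | None = None
    fovea_width: float | None = None
    boundary_waviness: float = 3.0
    mean_layer_thicknesses: tuple[float, ...] | None = None
    integer_traces: bool = False

    def resolve(self) -> "PhantomSpec":
        """Fill profile-dependent defaults and return a concrete spec."""
        d = _DEFAULTS[get_profile(self.profile).name]
        return replace(
            self,
            fovea_depth=self.fovea_depth if self.fovea_depth is not None else d["fovea_depth"],
            fovea_width=self.fovea_width if self.fovea_width is not None else d["fovea_width"],
            mean_layer_thicknesses=(
                tuple(self.mean_layer_thicknesses)
                if self.mean_layer_thicknesses is not None
                else d["thicknesses"]
            ),
        )


@dataclass
class BoundarySet:
    """Ordered per-column boundary traces.

    ``traces`` has shape ``(n_boundaries, width)``; entries are real-valued
    row positions, NaN where a boundary is undefined at a column.  Wherever
    two consecutive traces are both defined, ``traces[k] <= traces[k+1]``
    (tangency allowed, e.g. at the foveal pit).
    """

    profile: str
    traces: np.ndarray

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces, dtype=float)
        if self.traces.ndim != 2:
            raise ValueError("traces must be a 2-D (n_boundaries, width) array")
        p = get_profile(self.profile)
        if self.traces.shape[0] != p.n_boundaries:
            raise ValueError(
                f"profile {p.name!r} expects {p.n_boundaries} boundaries, "
                f"got {self.traces.shape[0]}"
            )

    @property
    def width(self) -> int:
        return self.traces.shape[1]

    @property
    def n_boundaries(self) -> int:
        return self.traces.shape[0]

    @property
    def layer_names(self) -> tuple[str, ...]:
        return get_profile(self.profile).layer_names

    @property
    def boundary_names(self) -> tuple[str, ...]:
        return get_profile(self.profile).boundary_names

    def validate_order(self, tol: float = 1e-9) -> None:
        upper = self.traces[:-1]
        lower = self.traces[1:]
        both = np.isfinite(upper) & np.isfinite(lower)
        if np.any(upper[both] > lower[both] + tol):
            k, = np.where(np.any((upper > lower + tol) & both, axis=1))
            raise BoundaryOrderError(
                f"boundary {k[0]} crosses boundary {k[0] + 1}"
            )


@dataclass
class BScan:
    """A single grayscale B-scan with intensities in [0, 1]."""

    pixels: np.ndarray
    provenance: PhantomSpec | str | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D grid")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixel intensities must be finite")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def _smooth_curve(rng: np.random.Generator, width: int, amplitude: float) -> np.ndarray:
    """Low-frequency random undulation with |curve| <= amplitude.

    Built from three cosine harmonics with random phase; the column-to-column
    increment is bounded by ~2*pi*f*amplitude/width, i.e. far below one pixel
    for any realistic width.
    """
    x = np.linspace(0.0, 1.0, width)
    curve = np.zeros(width)
    for j, cycles in enumerate((0.6, 1.1, 1.9)):
        phase = rng.uniform(0.0, 2.0 * np.pi)
        curve += np.cos(2.0 * np.pi * cycles * x + phase) / (j + 1)
    peak = np.abs(curve).max()
    if peak > 0:
        curve *= amplitude / peak
    return curve


def _validate(spec: PhantomSpec, profile: Profile) -> None:
    if spec.width < 2 or spec.height < 2:
        raise PhantomGeometryError("image must be at least 2x2 pixels")
    th = spec.mean_layer_thicknesses
    if len(th) != profile.n_layers:
        raise PhantomGeometryError(
            f"profile {profile.name!r} has {profile.n_layers} regions, "
            f"got {len(th)} thicknesses"
        )
    if any(t <= 0 for t in th):
        raise PhantomGeometryError("mean thicknesses must be positive")
    if spec.speckle_level < 0 or spec.boundary_waviness < 0:
        raise PhantomGeometryError("noise/waviness levels must be non-negative")
    margin = 4.0 * spec.boundary_waviness + 2.0
    if sum(th) + margin > spec.height:
        raise PhantomGeometryError(
            f"mean thicknesses sum to {sum(th):.0f} px which, with a "
            f"{margin:.0f} px waviness margin, exceeds the {spec.height} px height"
        )
    weights = _DEFAULTS[profile.name]["pit_weights"]
    inner = sum(t for t, w in zip(th, weights) if w > 0)
    if spec.fovea_depth >= inner:
        raise PhantomGeometryError(
            f"fovea_depth {spec.fovea_depth:.0f} px must be smaller than the "
            f"{inner:.0f} px of inner-region thickness"
        )
    if spec.fovea_width <= 0:
        raise PhantomGeometryError("fovea_width must be positive")


def generate_phantom(spec: PhantomSpec) -> tuple[BScan, BoundarySet]:
    """Generate one synthetic B-scan and its ground-truth boundaries.

    Deterministic for a fixed spec (single seeded random stream, no global
    state).  Boundaries are built bottom-up from per-region thickness
    profiles, which guarantees the anatomical ordering by construction; the
    foveal pit subtracts a Gaussian bump from the inner-region thicknesses
    (clipped at zero, so tangency — a vanished layer — is allowed).
    """
    spec = spec.resolve()
    profile = get_profile(spec.profile)
    _validate(spec, profile)

    rng = np.random.default_rng(spec.seed)
    n_regions = profile.n_layers
    cols = np.arange(spec.width, dtype=float)

    total = float(sum(spec.mean_layer_thicknesses))
    curvature = _smooth_curve(rng, spec.width, 2.0 * spec.boundary_waviness)
    bottom = (spec.height + total) / 2.0 + curvature

    sigma = spec.fovea_width / 2.355  # fovea_width is the pit FWHM
    pit = np.exp(-0.5 * ((cols - spec.width / 2.0) / sigma) ** 2)
    weights = _DEFAULTS[profile.name]["pit_weights"]

    traces = np.empty((profile.n_boundaries, spec.width))
    traces[-1] = bottom
    for k in range(n_regions - 1, -1, -1):
        wobble = _smooth_curve(rng, spec.width, 0.5 * spec.boundary_waviness)
        thickness = np.clip(
            spec.mean_layer_thicknesses[k]
            + wobble
            - spec.fovea_depth * weights[k] * pit,
            0.0,
            None,
        )
        traces[k] = traces[k + 1] - thickness

    if spec.integer_traces:
        traces = np.round(traces)
    if traces.min() < 0 or traces.max() >= spec.height:
        raise PhantomGeometryError("generated boundaries fall outside the image")

    boundaries = BoundarySet(profile=profile.name, traces=traces)
    labels = boundaries_to_classmap(boundaries, spec.height)

    image = np.full((spec.height, spec.width), _BACKGROUND_INTENSITY)
    for k, level in enumerate(_INTENSITIES[profile.name]):
        image[labels == k + 1] = level
    if spec.speckle_level > 0:
        shape = 1.0 / spec.speckle_level**2  # mean 1, sd = speckle_level
        image = image * rng.gamma(shape, 1.0 / shape, size=image.shape)
    np.clip(image, 0.0, 1.0, out=image)

    return BScan(pixels=image, provenance=spec), boundaries


def snap_traces(traces: np.ndarray) -> np.ndarray:
    """Snap real-valued traces to their nearest pixel row (ties upward)."""
    return np.ceil(np.asarray(traces, dtype=float) - 0.5)


def boundaries_to_classmap(boundaries: BoundarySet, height: int) -> np.ndarray:
    """Rasterize boundary traces into a per-pixel layer label map.

    Returns an ``(height, width)`` int array: 0 = background, ``k+1`` = the
    k-th layer region of the profile.  Region k occupies the half-open row
    band between its snapped bounding traces; columns where either trace is
    undefined get background for that region, and tangent traces produce a
    zero-thickness (absent) region.
    """
    boundaries.validate_order()
    snapped = snap_traces(boundaries.traces)
    width = boundaries.width
    labels = np.zeros((height, width), dtype=np.int32)
    rows = np.arange(height)[:, None]
    for k in range(boundaries.n_boundaries - 1):
        lo, hi = snapped[k], snapped[k + 1]
        defined = np.isfinite(lo) & np.isfinite(hi)
        lo_f = np.where(defined, lo, height)
        hi_f = np.where(defined, hi, -1)
        labels[(rows >= lo_f) & (rows < hi_f)] = k + 1
    return labels


def write_boundaries_csv(boundaries: BoundarySet, path) -> None:
    """Write defined trace samples as (boundary_index, column, row) rows."""
    idx, col = np.nonzero(np.isfinite(boundaries.traces))
    pd.DataFrame(
        {
            "boundary_index": idx,
            "column": col,
            "row": boundaries.traces[idx, col],
        }
    ).to_csv(path, index=False)


def read_boundaries_csv(path, profile: str, width: int | None = None) -> BoundarySet:
    """Read a boundary CSV written by :func:`write_boundaries_csv`."""
    df = pd.read_csv(path)
    p = get_profile(profile)
    if width is None:
        width = int(df["column"].max()) + 1
    traces = np.full((p.n_boundaries, width), np.nan)
    bi = df["boundary_index"].to_numpy(dtype=int)
    if bi.size and (bi.min() < 0 or bi.max() >= p.n_boundaries):
        raise ValueError(f"boundary_index out of range for profile {p.name!r}")
    traces[bi, df["column"].to_numpy(dtype=int)] = df["row"].to_numpy(dtype=float)
    return BoundarySet(profile=p.name, traces=traces)
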