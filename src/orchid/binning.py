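"""Digital spatial-offset binning of 2D detector frames.

A spatially offset measurement is emulated on a 2D detector by summing
pixels inside annular rings centred on the excitation axis: the ring radius
(in pixels, hence in sample-plane millimetres through the pixel pitch)
plays the role of the source-to-detector separation of classical offset
Raman spectroscopy.  Masks are *binary*: a pixel is a point at its centre
and either belongs to a ring or does not; membership uses the half-open
rule ``r_inner <= r < r_outer`` so that contiguous rings partition the
disk exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "RadialMask",
    "OffsetBinningScheme",
    "OffsetProfile",
    "make_radial_mask",
    "bin_frame",
    "binning_oracle",
    "default_center",
    "mask_to_tiff",
]

ANNULUS = "annulus"
CUMULATIVE = "cumulative_disk"


def default_center(shape: tuple[int, int]) -> tuple[float, float]:
    """Geometric centre of the pixel grid, ``((n_rows-1)/2, (n_cols-1)/2)``.

    Fractional on even-sized detectors so the mask is symmetric.
    """
    return ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)


@lru_cache(maxsize=16)
def _radius_grid(shape: tuple[int, int], center: tuple[float, float]) -> np.ndarray:
    rows = np.arange(shape[0], dtype=float) - center[0]
    cols = np.arange(shape[1], dtype=float) - center[1]
    return np.hypot(rows[:, None], cols[None, :])


@dataclass(frozen=True)
class RadialMask:
    """Binary annular mask on a pixel raster.

    ``raster`` is True exactly where ``r_inner <= r < r_outer`` with ``r``
    the Euclidean distance from the pixel centre to ``center`` (fractional
    pixel coordinates allowed).
    """

    center: tuple[float, float]
    r_inner: float
    r_outer: float
    raster: np.ndarray

    @property
    def n_pixels(self) -> int:
        return int(self.raster.sum())


def make_radial_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    r_inner: float,
    r_outer: float,
) -> RadialMask:
    """Build the binary mask selecting pixels with ``r_inner <= r < r_outer``."""
    if shape[0] <= 0 or shape[1] <= 0:
        raise ValueError(f"shape must be positive, got {shape}")
    if r_inner < 0 or r_outer < 0:
        raise ValueError(f"radii must be nonnegative, got ({r_inner}, {r_outer})")
    if r_inner >= r_outer:
        raise ValueError(
            f"inner radius must be strictly smaller than outer ({r_inner} >= {r_outer})"
        )
    r = _radius_grid(tuple(shape), (float(center[0]), float(center[1])))
    raster = (r >= r_inner) & (r < r_outer)
    return RadialMask((float(center[0]), float(center[1])), float(r_inner), float(r_outer), raster)


@dataclass(frozen=True)
class OffsetBinningScheme:
    """An ordered set of offset bins, either annuli or cumulative disks.

    In ``annulus`` mode the rings must be contiguous and non-overlapping
    (each outer radius equals the next inner radius) so that they partition
    the covered disk.  In ``cumulative_disk`` mode every bin is a full disk
    ``(0, R_k)`` with strictly increasing ``R_k``.
    """

    annuli: tuple[tuple[float, float], ...]
    mode: str = ANNULUS

    def __post_init__(self):
        if self.mode not in (ANNULUS, CUMULATIVE):
            raise ValueError(f"unknown binning mode {self.mode!r}")
        if not self.annuli:
            raise ValueError("scheme needs at least one bin")
        ann = tuple((float(a), float(b)) for a, b in self.annuli)
        object.__setattr__(self, "annuli", ann)
        for a, b in ann:
            if a < 0 or a >= b:
                raise ValueError(f"invalid bin ({a}, {b}): need 0 <= inner < outer")
        if self.mode == ANNULUS:
            for (a0, b0), (a1, b1) in zip(ann[:-1], ann[1:]):
                if b0 != a1:
                    raise ValueError(
                        f"annuli must be contiguous: outer {b0} != next inner {a1}"
                    )
        else:
            for (a, b), (a2, b2) in zip(ann[:-1], ann[1:]):
                if a != 0 or a2 != 0 or b2 <= b:
                    raise ValueError("cumulative disks must be (0, R_k) with increasing R_k")
            if ann[0][0] != 0:
                raise ValueError("cumulative disks must start at radius 0")

    @classmethod
    def from_width(
        cls,
        r_max: float,
        width: float = 1.0,
        r_min: float = 0.0,
        mode: str = ANNULUS,
    ) -> "OffsetBinningScheme":
        """Equal-width rings (or nested disks) between ``r_min`` and ``r_max``."""
        if width <= 0:
            raise ValueError("width must be positive")
        edges = np.arange(r_min, r_max + width / 2, width)
        if edges[-1] < r_max:
            edges = np.append(edges, r_max)
        if mode == ANNULUS:
            annuli = tuple(zip(edges[:-1], edges[1:]))
        else:
            annuli = tuple((0.0, e) for e in edges[1:])
        return cls(annuli, mode=mode)

    @property
    def n_bins(self) -> int:
        return len(self.annuli)

    @property
    def outer_radii(self) -> np.ndarray:
        return np.array([b for _, b in self.annuli])

    @property
    def mean_radii(self) -> np.ndarray:
        return np.array([(a + b) / 2 for a, b in self.annuli])

    def is_contiguous_from_zero(self) -> bool:
        return self.mode == ANNULUS and self.annuli[0][0] == 0.0


@dataclass
class OffsetProfile:
    """Per-bin summed intensity of one frame under a binning scheme."""

    scheme: OffsetBinningScheme
    sums: np.ndarray
    pixel_counts: np.ndarray
    center: tuple[float, float]

    def __post_init__(self):
        if len(self.sums) != self.scheme.n_bins:
            raise ValueError("profile length does not match scheme")


def _frame_data(frame) -> np.ndarray:
    data = getattr(frame, "data", frame)
    return np.asarray(data)


def bin_frame(frame, scheme: OffsetBinningScheme, center=None) -> OffsetProfile:
    """Sum frame pixels inside every bin of ``scheme``.

    Integer frames are accumulated in int64 so the result is exact; float
    frames are accumulated in float64.  The frame may be a raw 2D array or
    any object with a 2D ``.data`` attribute.
    """
    data = _frame_data(frame)
    if data.ndim != 2:
        raise ValueError(f"expected a 2D frame, got shape {data.shape}")
    shape = data.shape
    if center is None:
        center = default_center(shape)
    center = (float(center[0]), float(center[1]))
    r = _radius_grid(shape, center)

    integer = np.issubdtype(data.dtype, np.integer) or np.issubdtype(data.dtype, np.bool_)
    acc_dtype = np.int64 if integer else np.float64

    if scheme.mode == ANNULUS:
        # contiguous edges -> one digitize pass
        edges = np.array([scheme.annuli[0][0]] + [b for _, b in scheme.annuli])
        idx = np.searchsorted(edges, r.ravel(), side="right") - 1
        valid = (idx >= 0) & (idx < scheme.n_bins) & (r.ravel() < edges[-1]) & (
            r.ravel() >= edges[0]
        )
        flat = data.ravel()
        sums = np.zeros(scheme.n_bins, dtype=acc_dtype)
        np.add.at(sums, idx[valid], flat[valid].astype(acc_dtype))
        counts = np.bincount(idx[valid], minlength=scheme.n_bins).astype(np.int64)
    else:
        radii = scheme.outer_radii
        edges = np.concatenate(([0.0], radii))
        idx = np.searchsorted(edges, r.ravel(), side="right") - 1
        valid = (idx >= 0) & (idx < scheme.n_bins)
        flat = data.ravel()
        part = np.zeros(scheme.n_bins, dtype=acc_dtype)
        np.add.at(part, idx[valid], flat[valid].astype(acc_dtype))
        cpart = np.bincount(idx[valid], minlength=scheme.n_bins).astype(np.int64)
        sums = np.cumsum(part)
        counts = np.cumsum(cpart)
    return OffsetProfile(scheme, sums, counts, center)


def binning_oracle(frame, scheme: OffsetBinningScheme, center=None) -> OffsetProfile:
    """Reference implementation by explicit per-pixel iteration (tests only).

    Restricted to small frames; kept deliberately independent of
    :func:`bin_frame` internals.
    """
    data = _frame_data(frame)
    if data.shape[0] > 128 or data.shape[1] > 128:
        raise ValueError("oracle is restricted to frames up to 128x128")
    if center is None:
        center = default_center(data.shape)
    integer = np.issubdtype(data.dtype, np.integer) or np.issubdtype(data.dtype, np.bool_)
    sums = [0 if integer else 0.0 for _ in scheme.annuli]
    counts = [0 for _ in scheme.annuli]
    for i in range(data.shape[0]):
        for j in range(data.shape[1]):
            rr = ((i - center[0]) ** 2 + (j - center[1]) ** 2) ** 0.5
            for k, (a, b) in enumerate(scheme.annuli):
                if a <= rr < b:
                    sums[k] += data[i, j].item()
                    counts[k] += 1
    return OffsetProfile(
        scheme,
        np.array(sums, dtype=np.int64 if integer else np.float64),
        np.array(counts, dtype=np.int64),
        (float(center[0]), float(center[1])),
    )


def mask_to_tiff(mask: RadialMask, path) -> None:
    """Export a mask raster as an 8-bit TIFF (0/255) for visual inspection."""
    import tifffile

    tifffile.imwrite(
        str(path),
        (mask.raster.astype(np.uint8) * 255),
        software=False,
    )
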