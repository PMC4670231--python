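"""Lattice containers shared by every statistic in the package.

A grayscale image is read as a particle field: the intensity of a pixel is
the number of events (particles) it holds, up to the bit-depth saturation
limit (255 for 8-bit data).  All statistics are computed over an explicit
study region Omega, a boolean mask of the same shape; pixels outside the
mask contribute neither particles nor area.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field as _dc_field

import numpy as np


class DomainError(ValueError):
    """The input is structurally valid but outside the statistic's domain
    (e.g. fewer than two particles, empty study region)."""


@dataclass(frozen=True)
class DiscKernel:
    """Pixelated disc b(x, r): all integer offsets within Euclidean
    distance ``radius`` of the center pixel (boundary inclusive).

    The same geometry is used for the K-function neighbourhood, the Besag
    edge-correction areas and the granulometry structuring elements, so
    that "radius r" means one thing throughout the package.
    """

    radius: float
    offsets: np.ndarray  # (m, 2) int array of (di, dj)
    pixel_count: int  # |b(x, r)| for an unclipped disc
    ideal_area: float  # pi r^2

    @property
    def footprint(self) -> np.ndarray:
        """Boolean (2R+1, 2R+1) array of the disc, R = floor(radius)."""
        r_int = int(np.floor(self.radius))
        fp = np.zeros((2 * r_int + 1, 2 * r_int + 1), dtype=bool)
        fp[self.offsets[:, 0] + r_int, self.offsets[:, 1] + r_int] = True
        return fp

    @property
    def half_width(self) -> int:
        return int(np.floor(self.radius))


def make_disc_kernel(radius: float) -> DiscKernel:
    """Enumerate the pixelated disc of the given radius.

    Membership is ``di**2 + dj**2 <= radius**2`` between pixel centers, so
    ``radius=1`` gives the 5-pixel cross and ``radius=3`` gives 29 pixels
    against an ideal area of ``pi * 9 = 28.27``.
    """
    if not np.isfinite(radius) or radius <= 0:
        raise ValueError(f"radius must be positive and finite, got {radius!r}")
    r_int = int(np.floor(radius))
    di, dj = np.meshgrid(
        np.arange(-r_int, r_int + 1), np.arange(-r_int, r_int + 1), indexing="ij"
    )
    inside = di * di + dj * dj <= radius * radius
    offsets = np.stack([di[inside], dj[inside]], axis=1)
    return DiscKernel(
        radius=float(radius),
        offsets=offsets,
        pixel_count=int(inside.sum()),
        ideal_area=float(np.pi * radius * radius),
    )


@dataclass
class GrayField:
    """A 2-D particle field: integer intensities plus a study-region mask.

    Parameters
    ----------
    intensities
        2-D non-negative integer lattice; one intensity unit is one
        particle.  Values outside the mask are treated as zero by every
        statistic.
    mask
        Boolean lattice of the same shape; ``True`` marks pixels inside
        the study region Omega.  Defaults to the full lattice.
    bit_depth
        Saturation is ``2**bit_depth - 1`` particles per pixel (default 8,
        saturation 255).
    """

    intensities: np.ndarray
    mask: np.ndarray = None  # type: ignore[assignment]
    bit_depth: int = 8

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities)
        if arr.ndim != 2:
            raise ValueError(f"intensities must be 2-D, got shape {arr.shape}")
        if not np.issubdtype(arr.dtype, np.integer):
            if np.issubdtype(arr.dtype, np.floating) and np.all(arr == np.rint(arr)):
                arr = arr.astype(np.int64)
            else:
                raise ValueError("intensities must be integers (particle counts)")
        arr = arr.astype(np.int64, copy=False)
        if self.mask is None:
            mask = np.ones(arr.shape, dtype=bool)
        else:
            mask = np.asarray(self.mask, dtype=bool)
        if mask.shape != arr.shape:
            raise ValueError(
                f"mask shape {mask.shape} != intensities shape {arr.shape}"
            )
        saturation = (1 << int(self.bit_depth)) - 1
        if arr.min(initial=0) < 0 or arr.max(initial=0) > saturation:
            raise ValueError(
                f"intensities must lie in [0, {saturation}] for "
                f"bit_depth={self.bit_depth}"
            )
        self.intensities = arr
        self.mask = mask

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape

    @property
    def saturation(self) -> int:
        return (1 << int(self.bit_depth)) - 1

    @property
    def omega_area(self) -> int:
        """|Omega|: number of study-region pixels (pixel^2)."""
        return int(self.mask.sum())

    @property
    def masked_intensities(self) -> np.ndarray:
        """Intensities with out-of-mask pixels forced to zero."""
        return np.where(self.mask, self.intensities, 0)

    @property
    def n(self) -> int:
        """Total particle count over the study region."""
        return int(self.masked_intensities.sum())

    @property
    def density(self) -> float:
        """Mean particles per pixel over Omega."""
        area = self.omega_area
        if area == 0:
            raise DomainError("empty study region")
        return self.n / area

    def mask_signature(self) -> str:
        """Stable hash of the mask geometry, used to pair a field with a
        matched CSR reference."""
        h = hashlib.sha256()
        h.update(str(self.mask.shape).encode())
        h.update(np.packbits(self.mask).tobytes())
        return h.hexdigest()


def mask_signature_of(mask: np.ndarray) -> str:
    """Mask-geometry hash for a bare boolean lattice."""
    mask = np.asarray(mask, dtype=bool)
    h = hashlib.sha256()
    h.update(str(mask.shape).encode())
    h.update(np.packbits(mask).tobytes())
    return h.hexdigest()
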