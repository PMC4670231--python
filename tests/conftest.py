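"""Shared fixtures and independent oracle implementations.

The oracles deliberately avoid the package's filter-based evaluation
path: the grayscale K oracle is a direct double sum over pixel pairs, and
the binary K oracle is a classic point-pattern implementation over event
coordinates.  Both use squared integer distances so disc membership is
exact.
"""

from __future__ import annotations

import numpy as np
import pytest

from grayripley.field import GrayField, make_disc_kernel


def disc_area_brute(mask: np.ndarray, i: int, j: int, radius: float) -> int:
    """Count mask pixels within Euclidean distance ``radius`` of (i, j)."""
    rows, cols = np.nonzero(mask)
    d2 = (rows - i) ** 2 + (cols - j) ** 2
    return int((d2 <= radius * radius).sum())


def _correction(area: np.ndarray, kernel, method: str) -> np.ndarray:
    border = area < kernel.pixel_count
    c = np.ones(len(area))
    if method == "full_field":
        c = kernel.ideal_area / area
    elif method == "ideal_border":
        c[border] = kernel.ideal_area / area[border]
    else:
        c[border] = kernel.pixel_count / area[border]
    return c


def k_double_sum(field: GrayField, radius: float, method: str) -> float:
    """Direct double-sum grayscale K over all mask-pixel pairs."""
    kernel = make_disc_kernel(radius)
    coords = np.argwhere(field.mask)
    p = field.intensities[field.mask].astype(np.float64)
    n = p.sum()
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
    within = d2 <= radius * radius  # includes the diagonal
    area = within.sum(axis=1)  # A_xr (center pixel included)
    c = _correction(area, kernel, method)
    s = within @ p - p  # neighbours only
    total = float((c * p * (p - 1.0 + s)).sum())
    return field.omega_area / (n * (n - 1.0)) * total


def k_point_pattern(field: GrayField, radius: float, method: str) -> float:
    """Classic Ripley K of the point set of unit-intensity pixels, with
    Besag-style corrections computed against the study-region mask."""
    kernel = make_disc_kernel(radius)
    points = np.argwhere(field.mask & (field.intensities == 1))
    n = len(points)
    d2 = ((points[:, None, :] - points[None, :, :]) ** 2).sum(axis=2)
    within = (d2 <= radius * radius) & ~np.eye(n, dtype=bool)
    area = np.array(
        [disc_area_brute(field.mask, i, j, radius) for i, j in points]
    )
    c = _correction(area, kernel, method)
    total = float((c * within.sum(axis=1)).sum())
    return field.omega_area / (n * (n - 1.0)) * total


def random_small_field(
    rng: np.random.Generator,
    max_side: int = 16,
    binary: bool = False,
    with_mask: bool = True,
) -> GrayField:
    """Random small field with at least two particles and a nonempty
    (possibly ragged) study region."""
    while True:
        shape = (int(rng.integers(4, max_side + 1)), int(rng.integers(4, max_side + 1)))
        if binary:
            intensities = (rng.random(shape) < 0.4).astype(np.int64)
        else:
            intensities = rng.integers(0, 8, size=shape)
            if rng.random() < 0.3:  # occasionally hit high intensities
                intensities *= 30
        mask = rng.random(shape) < 0.8 if with_mask else np.ones(shape, bool)
        if mask.sum() < 2:
            continue
        field = GrayField(intensities, mask=mask)
        if field.n >= 2 and (not binary or field.n >= 2):
            return field


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
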