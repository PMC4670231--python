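"""Concrete (segmentation-based) characterization of aggregates.

The K-function module answers *whether* and *how much* a field is
aggregated; this module answers *what the aggregates look like*:
granulometry (pattern spectrum) for dominant object sizes, a
background-subtract / max-entropy-threshold / close segmentation
pipeline, the TET/TEE bivariate similarity index against ground truth,
and the preprocessing used on experimental images (three-class Otsu
masking, ensemble averaging of K~ profiles across stacks).

All morphology uses the same inclusive pixelated disc as the K-function
(:func:`grayripley.field.make_disc_kernel`), so "radius r" has one
meaning across the abstract and concrete statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as _ndi
from scipy import signal as _signal
from skimage.filters import threshold_multiotsu
from skimage.morphology import opening as _gray_opening

from .field import DomainError, GrayField, make_disc_kernel
from .kfunction import KProfile


@dataclass
class GranulometricProfile:
    """Retained total intensity after opening at increasing disc radii.

    ``sums[0]`` is the raw image sum (radius 0 = no opening); openings are
    anti-extensive, so ``sums`` is nonincreasing.  ``derivative[i] =
    sums[i+1] - sums[i]`` is the (negative) mass removed by the opening at
    radius ``radii[i+1]``, so a trough at radius t marks objects of size
    class t - 1: a disc-shaped object of radius R survives the opening at
    R and vanishes at R + 1, and is extracted by
    :func:`extract_size_class` at radius R.
    """

    radii: np.ndarray  # 0..max_radius
    sums: np.ndarray

    @property
    def derivative(self) -> np.ndarray:
        return np.diff(self.sums)


def _open(intensities: np.ndarray, radius: int) -> np.ndarray:
    return _gray_opening(
        intensities.astype(np.uint8), make_disc_kernel(radius).footprint
    ).astype(np.int64)


def granulometric_profile(field: GrayField, max_radius: int) -> GranulometricProfile:
    """Pattern spectrum: total intensity retained after opening with disc
    structuring elements of radii 0..max_radius.

    Pixelated Euclidean discs are not a perfectly absorbing family (an
    opening at a larger radius can restore boundary pixels that a smaller
    one removed), so the size distribution is made properly decreasing by
    taking, at each radius, the pixelwise minimum over all openings up to
    that radius.  Wherever the disc family is absorbing this equals the
    plain opening; elsewhere it cancels the restoration artifacts that
    would otherwise blur size-class troughs.
    """
    if max_radius < 1:
        raise ValueError("max_radius must be >= 1")
    img = field.masked_intensities
    sums = [int(img.sum())]
    current = img.copy()
    for r in range(1, max_radius + 1):
        current = np.minimum(current, _open(img, r))
        sums.append(int(current.sum()))
    return GranulometricProfile(
        radii=np.arange(max_radius + 1), sums=np.asarray(sums, dtype=np.int64)
    )


def detect_troughs(
    profile: GranulometricProfile, prominence: float | None = None
) -> list[int]:
    """Major troughs of the granulometric derivative: interior local
    minima with prominence at least ``prominence`` (default 5% of the
    derivative's total range).

    A trough at radius t means the opening at t removed a dominant burst
    of mass, i.e. a dominant object size class of radius about t - 1.
    """
    d = profile.derivative
    if len(d) < 3:
        raise ValueError("profile needs at least 3 radius entries")
    rng = float(d.max() - d.min())
    if rng == 0:
        return []
    if prominence is None:
        prominence = 0.05 * rng
    idx, _ = _signal.find_peaks(-d.astype(np.float64), prominence=prominence)
    return [int(profile.radii[i + 1]) for i in idx]


def extract_size_class(field: GrayField, radius: int) -> GrayField:
    """Objects of one size class: open(r) - open(r+1), elementwise
    (clamped at zero where disc pixelation makes the larger opening
    locally exceed the smaller one)."""
    if radius < 1:
        raise ValueError("radius must be >= 1")
    img = field.masked_intensities
    out = np.maximum(_open(img, radius) - _open(img, radius + 1), 0)
    return GrayField(out, mask=field.mask, bit_depth=field.bit_depth)


def rolling_ball_background(field: GrayField, ball_radius: int = 50) -> GrayField:
    """Background-subtracted image, with the background estimated by
    grayscale opening with a disc of ``ball_radius`` (a flat-ball
    approximation of the classic rolling-ball subtraction; radius default
    matches the common 50 px convention)."""
    if ball_radius < 1:
        raise ValueError("ball_radius must be >= 1")
    img = field.masked_intensities
    out = img - _open(img, ball_radius)
    return GrayField(out, mask=field.mask, bit_depth=field.bit_depth)


def max_entropy_threshold(field: GrayField) -> int:
    """Kapur maximum-entropy threshold over the 256-bin histogram of
    in-mask pixels.

    Maximizes H_background(t) + H_foreground(t); foreground is ``> t``.
    Ties break to the smallest threshold.
    """
    values = field.masked_intensities[field.mask]
    hist = np.bincount(values, minlength=field.saturation + 1).astype(np.float64)
    if np.count_nonzero(hist) < 2:
        raise DomainError("need at least two distinct intensities to threshold")
    p = hist / hist.sum()
    # plogp with 0 log 0 = 0
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    cum_p = np.cumsum(p)
    cum_plogp = np.cumsum(plogp)
    total_plogp = cum_plogp[-1]
    # candidate thresholds t: both sides must contain probability mass
    t = np.arange(len(p) - 1)
    p0 = cum_p[t]
    p1 = 1.0 - p0
    valid = (p0 > 0) & (p1 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        h0 = np.log(p0) - cum_plogp[t] / p0
        h1 = np.log(p1) - (total_plogp - cum_plogp[t]) / p1
    score = np.where(valid, h0 + h1, -np.inf)
    return int(np.argmax(score))  # argmax returns the first (smallest) maximizer


def segment_pipeline(
    field: GrayField, ball_radius: int = 50, close_radius: int = 1
) -> np.ndarray:
    """Background subtraction, max-entropy thresholding, then a binary
    close with edge padding (the lattice border is treated as foreground
    during the closing, so border objects are not eroded away).

    Returns the boolean aggregate mask.
    """
    sub = rolling_ball_background(field, ball_radius)
    t = max_entropy_threshold(sub)
    binary = sub.masked_intensities > t
    if close_radius > 0:
        fp = make_disc_kernel(close_radius).footprint
        pad = close_radius
        padded = np.pad(binary, pad, mode="constant", constant_values=True)
        closed = _ndi.binary_erosion(
            _ndi.binary_dilation(padded, structure=fp), structure=fp
        )
        binary = closed[pad:-pad, pad:-pad]
    return binary & field.mask


@dataclass(frozen=True)
class SimilarityResult:
    """Bivariate similarity of an estimated mask against ground truth.

    TET = |T n E| / |T| (how much of the truth was found);
    TEE = |T n E| / |E| (how much of the estimate is real), with TEE = 1
    for an empty estimate.
    """

    tet: float
    tee: float
    t_count: int
    e_count: int
    overlap_count: int


def tet_tee(truth: np.ndarray, estimate: np.ndarray) -> SimilarityResult:
    """TET/TEE overlap indices of two same-shape boolean masks."""
    truth = np.asarray(truth, dtype=bool)
    estimate = np.asarray(estimate, dtype=bool)
    if truth.shape != estimate.shape:
        raise ValueError(
            f"shape mismatch: truth {truth.shape} vs estimate {estimate.shape}"
        )
    t = int(truth.sum())
    if t == 0:
        raise DomainError("empty truth mask: TET is undefined")
    e = int(estimate.sum())
    overlap = int((truth & estimate).sum())
    tee = 1.0 if e == 0 else overlap / e
    return SimilarityResult(
        tet=overlap / t, tee=tee, t_count=t, e_count=e, overlap_count=overlap
    )


def three_class_otsu(field: GrayField) -> GrayField:
    """Three-class Otsu masking for experimental images.

    Finds two thresholds t1 < t2 minimizing intra-class variance over
    three classes; the lower two classes (background and the ambiguous
    middle class) are zeroed, the top class keeps its original intensity.
    The returned field's study region is the set of surviving (nonzero)
    pixels, ready for K-function analysis with the nonzero-mask policy.
    """
    values = field.masked_intensities[field.mask]
    if len(np.unique(values)) < 3:
        raise DomainError("need at least three distinct intensities")
    t1, t2 = threshold_multiotsu(values, classes=3, nbins=field.saturation + 1)
    out = np.where(field.mask & (field.intensities > t2), field.intensities, 0)
    return GrayField(out, mask=out > 0, bit_depth=field.bit_depth)


def ensemble_average(profiles: list[KProfile]) -> KProfile:
    """Arithmetic mean of K and K~ per radius across stacks of one cell.

    All profiles must share radii and edge method; ``n`` and
    ``omega_area`` of the result are the rounded means (diagnostic only).
    """
    if not profiles:
        raise ValueError("need at least one profile")
    first = profiles[0]
    for p in profiles[1:]:
        if not np.array_equal(p.radii, first.radii):
            raise ValueError("profiles have mismatched radii")
        if p.edge_method != first.edge_method:
            raise ValueError("profiles have mismatched edge methods")
    return KProfile(
        radii=first.radii.copy(),
        k_values=np.mean([p.k_values for p in profiles], axis=0),
        ktilde_values=np.mean([p.ktilde_values for p in profiles], axis=0),
        n=int(round(np.mean([p.n for p in profiles]))),
        omega_area=int(round(np.mean([p.omega_area for p in profiles]))),
        edge_method=first.edge_method,
    )


def construct_summary(per_cell: list[float]) -> tuple[float, float]:
    """Mean and standard error of the mean over per-cell values."""
    values = np.asarray(per_cell, dtype=np.float64)
    if values.size == 0:
        raise ValueError("need at least one value")
    mean = float(values.mean())
    sem = 0.0 if values.size == 1 else float(values.std(ddof=1) / np.sqrt(values.size))
    return mean, sem
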