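"""Synthetic validation fields.

Generators for the study conditions used to validate the grayscale
K-function: complete spatial randomness (CSR) at controlled densities,
circular-cluster fields parameterized by the Aggregate-to-Diffuse Ratio
(ADR) and Signal-to-Background Ratio (SBR), confocal-style degradation
(Gaussian PSF followed by per-pixel Poisson noise), and CSR on decimated
study regions.

Every generator conditions on an exact total particle count (multinomial
occupancy over the study region) and is bit-reproducible from its
``seed``.  Per-pixel counts saturate at 255 (8-bit); any excess particles
are discarded with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as _ndi

from .field import DiscKernel, DomainError, GrayField, make_disc_kernel

SATURATION = 255


@dataclass(frozen=True)
class ClusterSpec:
    """Parameters of a clustered particle field.

    Exactly one of ``adr``, ``n_clusters`` or ``sbr`` may be left ``None``;
    the missing one is derived from the relation
    ``ADR = SBR * A_clusters / A_field``, where ``A_clusters`` is the
    realized union area of the cluster discs.  ``mode`` is an optional
    annotation naming which sweep the spec belongs to (``"vary_n_agg"`` or
    ``"vary_sbr"``); it does not affect generation.
    """

    shape: tuple[int, int] = (256, 256)
    n_clusters: int | None = None
    cluster_radius: float = 8.0
    adr: float | None = None
    sbr: float | None = None
    background_density: float = 1.0
    mode: str | None = None


@dataclass(frozen=True)
class MicroscopeSpec:
    """Confocal-style degradation: truncated-Gaussian PSF and Poisson
    noise.

    ``snr`` is a *diagnostic*, not a knob: per-pixel Poisson noise with
    lambda equal to the pixel value leaves no free noise amplitude, so a
    target SNR is realized by choosing signal and background levels such
    that S / sqrt(S + B) matches it (see :func:`poisson_snr`).
    """

    psf_diameter: int = 3
    psf_sigma: float = 1.0
    snr: float | None = None

    def __post_init__(self) -> None:
        if self.psf_diameter % 2 == 0 or self.psf_diameter < 1:
            raise ValueError("psf_diameter must be a positive odd integer")
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be positive")
        if self.snr is not None and self.snr <= 0:
            raise ValueError("snr must be positive when given")


@dataclass(frozen=True)
class DecimationSpec:
    """Randomly scattered circular holes cut out of the study region."""

    n_decimations: int
    decimation_radius: float = 20.0
    min_offset: int = 1


def poisson_snr(signal_density: float, background_density: float) -> float:
    """SNR of a Poisson-noised aggregate pixel: S / sqrt(S + B)."""
    return signal_density / float(np.sqrt(signal_density + background_density))


def csr_intensities(mask: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Place exactly ``n`` particles uniformly over mask-true pixels.

    Each particle lands independently on one of the |Omega| pixels
    (multinomial occupancy); counts clip at 255 and clipped particles are
    discarded with a warning.
    """
    mask = np.asarray(mask, dtype=bool)
    omega = int(mask.sum())
    if omega == 0:
        raise DomainError("empty study region")
    if n > SATURATION * omega:
        raise DomainError(
            f"cannot hold {n} particles on {omega} pixels at saturation {SATURATION}"
        )
    counts = np.bincount(rng.integers(0, omega, size=int(n)), minlength=omega)
    if counts.max(initial=0) > SATURATION:
        lost = int(np.clip(counts - SATURATION, 0, None).sum())
        warnings.warn(
            f"{lost} particles discarded at the {SATURATION}-particle "
            "saturation limit",
            stacklevel=2,
        )
        counts = np.minimum(counts, SATURATION)
    out = np.zeros(mask.shape, dtype=np.int64)
    out[mask] = counts
    return out


def simulate_csr(
    shape: tuple[int, int] = (256, 256),
    density: float | None = None,
    n: int | None = None,
    mask: np.ndarray | None = None,
    seed: int = 0,
) -> GrayField:
    """CSR field with ``n = round(density * |Omega|)`` particles (or an
    explicit ``n``) placed uniformly over the study region."""
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if (density is None) == (n is None):
        raise ValueError("give exactly one of density or n")
    if n is None:
        if density <= 0:
            raise ValueError("density must be positive")
        n = int(round(density * mask.sum()))
    if n < 2:
        raise DomainError("fewer than two particles requested")
    rng = np.random.default_rng(seed)
    return GrayField(csr_intensities(mask, n, rng), mask=mask)


def _place_cluster_mask(
    shape: tuple[int, int],
    n_clusters: int,
    kernel: DiscKernel,
    rng: np.random.Generator,
) -> np.ndarray:
    """Union mask of ``n_clusters`` discs placed uniformly, fully inside
    the lattice; cluster-cluster overlap is permitted."""
    h = kernel.half_width
    nrow, ncol = shape
    if nrow - 2 * h <= 0 or ncol - 2 * h <= 0:
        raise DomainError(
            f"clusters of radius {kernel.radius} do not fit a {shape} lattice"
        )
    truth = np.zeros(shape, dtype=bool)
    for _ in range(n_clusters):
        ci = int(rng.integers(h, nrow - h))
        cj = int(rng.integers(h, ncol - h))
        truth[ci - h : ci + h + 1, cj - h : cj + h + 1] |= kernel.footprint
    return truth


def simulate_clusters(
    spec: ClusterSpec, seed: int = 0
) -> tuple[GrayField, np.ndarray]:
    """Clustered field: a diffuse CSR pool over the whole lattice plus an
    aggregate pool distributed CSR within randomly placed discs.

    The diffuse pool has ``background_density * A_field`` particles and
    covers cluster pixels too (the signal is *added to* the background, so
    expected intensity inside clusters is ``background * (1 + SBR)``).
    Returns the field and the ground-truth disc mask.
    """
    rng = np.random.default_rng(seed)
    nrow, ncol = spec.shape
    a_field = nrow * ncol
    b = spec.background_density
    if b < 0:
        raise ValueError("background_density must be >= 0")
    free = [name for name, v in (("adr", spec.adr), ("n_clusters", spec.n_clusters), ("sbr", spec.sbr)) if v is None]
    if len(free) != 1:
        raise ValueError(
            "exactly one of adr, n_clusters, sbr must be left None "
            f"(got free: {free or 'none'})"
        )
    kernel = make_disc_kernel(spec.cluster_radius)

    if spec.adr is not None and spec.adr == 0:
        full = np.ones(spec.shape, dtype=bool)
        n_bg = int(round(b * a_field))
        if n_bg < 2:
            raise DomainError("fewer than two particles in the derived field")
        return GrayField(csr_intensities(full, n_bg, rng)), np.zeros(
            spec.shape, dtype=bool
        )

    if spec.n_clusters is None:
        # derive the cluster count from ADR = SBR * A_c / A_field
        target_area = spec.adr * a_field / spec.sbr
        n_clusters = max(1, int(round(target_area / kernel.pixel_count)))
    else:
        n_clusters = int(spec.n_clusters)
    truth = _place_cluster_mask(spec.shape, n_clusters, kernel, rng)
    a_c = int(truth.sum())

    n_bg = int(round(b * a_field))
    if spec.adr is not None:
        # honor the requested ADR exactly; SBR is then realized only up to
        # the quantization of the cluster count / union area
        if n_bg == 0:
            raise DomainError(
                "cannot realize the requested ADR: no diffuse pool "
                f"(background density {b})"
            )
        n_agg = int(round(spec.adr * n_bg))
        if n_agg > 0 and a_c == 0:
            raise DomainError(
                "cannot realize the requested ADR: empty cluster area"
            )
    else:  # adr free: derive the aggregate pool from SBR
        n_agg = int(round(spec.sbr * b * a_c))
    if n_bg + n_agg < 2:
        raise DomainError("fewer than two particles in the derived field")
    full = np.ones(spec.shape, dtype=bool)
    intensities = np.zeros(spec.shape, dtype=np.int64)
    if n_bg > 0:
        intensities += csr_intensities(full, n_bg, rng)
    if n_agg > 0:
        intensities += csr_intensities(truth, n_agg, rng)
    if intensities.max(initial=0) > SATURATION:
        lost = int(np.clip(intensities - SATURATION, 0, None).sum())
        warnings.warn(
            f"{lost} particles discarded at the {SATURATION}-particle "
            "saturation limit",
            stacklevel=2,
        )
        intensities = np.minimum(intensities, SATURATION)
    return GrayField(intensities), truth


def simulate_aggregates_only(
    shape: tuple[int, int],
    n_clusters: int,
    cluster_radius: float,
    n_particles: int,
    seed: int = 0,
) -> tuple[GrayField, np.ndarray]:
    """Pure-aggregate field (no diffuse pool): ``n_particles`` placed CSR
    within the union of ``n_clusters`` randomly located discs.

    The binary-pattern limit of this generator at low counts is the
    classic clustered point process used to study the correspondence
    between the K-maximizing radius and the true cluster radius.
    """
    rng = np.random.default_rng(seed)
    kernel = make_disc_kernel(cluster_radius)
    truth = _place_cluster_mask(shape, int(n_clusters), kernel, rng)
    if n_particles < 2:
        raise DomainError("fewer than two particles requested")
    intensities = np.zeros(shape, dtype=np.int64)
    intensities += csr_intensities(truth, int(n_particles), rng)
    return GrayField(intensities), truth


def simulate_size_classes(
    shape: tuple[int, int] = (256, 256),
    radii: tuple[float, ...] = (2, 4, 6, 8),
    n_per_class: int = 20,
    background_level: int = 2,
    signal_level: int = 20,
    seed: int = 0,
) -> tuple[GrayField, dict[float, np.ndarray]]:
    """Multi-size-class field for granulometric and segmentation analysis:
    ``n_per_class`` randomly placed flat aggregates at each radius on a
    uniform background.

    Aggregate pixels carry the signal added to the background
    (``background_level + signal_level``; SBR = signal/background),
    background pixels carry ``background_level``.  Pass the result through
    :func:`apply_psf` / :func:`apply_poisson_noise` for confocal-style
    degradation.  Returns the field and a dict mapping each class radius
    to its ground-truth disc mask.
    """
    rng = np.random.default_rng(seed)
    value = int(background_level) + int(signal_level)
    if value > SATURATION:
        raise ValueError("background + signal exceeds the saturation limit")
    intensities = np.full(shape, int(background_level), dtype=np.int64)
    truths: dict[float, np.ndarray] = {}
    for r in radii:
        kernel = make_disc_kernel(r)
        truth = _place_cluster_mask(shape, n_per_class, kernel, rng)
        truths[float(r)] = truth
        intensities = np.where(truth, value, intensities)
    return GrayField(intensities), truths


def gaussian_psf_kernel(diameter: int = 3, sigma: float = 1.0) -> np.ndarray:
    """Normalized truncated-Gaussian PSF on a ``diameter x diameter``
    grid."""
    if diameter % 2 == 0 or diameter < 1:
        raise ValueError("psf diameter must be a positive odd integer")
    h = diameter // 2
    di, dj = np.meshgrid(
        np.arange(-h, h + 1), np.arange(-h, h + 1), indexing="ij"
    )
    k = np.exp(-(di * di + dj * dj) / (2.0 * sigma * sigma))
    return k / k.sum()


def apply_psf(field: GrayField, spec: MicroscopeSpec) -> GrayField:
    """Convolve with the normalized truncated-Gaussian PSF
    (reflect-padded), then round back to integer counts in [0, 255]."""
    kernel = gaussian_psf_kernel(spec.psf_diameter, spec.psf_sigma)
    blurred = _ndi.convolve(
        field.masked_intensities.astype(np.float64), kernel, mode="reflect"
    )
    out = np.clip(np.rint(blurred), 0, field.saturation).astype(np.int64)
    return GrayField(np.where(field.mask, out, 0), mask=field.mask,
                     bit_depth=field.bit_depth)


def apply_poisson_noise(
    field: GrayField, spec: MicroscopeSpec | None = None, seed: int = 0
) -> GrayField:
    """Replace each pixel with a Poisson draw of mean equal to its value
    (independently per pixel), clipped to the saturation limit."""
    rng = np.random.default_rng(seed)
    noisy = rng.poisson(field.masked_intensities)
    if noisy.max(initial=0) > field.saturation:
        warnings.warn(
            f"Poisson draws clipped at the {field.saturation}-particle "
            "saturation limit",
            stacklevel=2,
        )
        noisy = np.minimum(noisy, field.saturation)
    return GrayField(np.where(field.mask, noisy, 0), mask=field.mask,
                     bit_depth=field.bit_depth)


def degrade(field: GrayField, spec: MicroscopeSpec, seed: int = 0,
            noise: bool = True) -> GrayField:
    """PSF blur followed (optionally) by Poisson noise."""
    out = apply_psf(field, spec)
    if noise:
        out = apply_poisson_noise(out, spec, seed=seed)
    return out


def decimated_mask(
    shape: tuple[int, int],
    spec: DecimationSpec,
    rng: np.random.Generator,
    max_attempts: int = 10_000,
) -> np.ndarray:
    """Study region with ``n_decimations`` circular holes of the given
    radius, each fully inside the lattice, pairwise offset by at least
    ``min_offset`` pixels (no overlap)."""
    kernel = make_disc_kernel(spec.decimation_radius)
    h = kernel.half_width
    nrow, ncol = shape
    min_dist = 2.0 * spec.decimation_radius + spec.min_offset
    centers: list[tuple[int, int]] = []
    attempts = 0
    while len(centers) < spec.n_decimations:
        if attempts >= max_attempts:
            raise DomainError(
                f"failed to place {spec.n_decimations} decimations of radius "
                f"{spec.decimation_radius} within {max_attempts} attempts"
            )
        attempts += 1
        ci = int(rng.integers(h, nrow - h))
        cj = int(rng.integers(h, ncol - h))
        if all((ci - a) ** 2 + (cj - b) ** 2 >= min_dist**2 for a, b in centers):
            centers.append((ci, cj))
    mask = np.ones(shape, dtype=bool)
    for ci, cj in centers:
        mask[ci - h : ci + h + 1, cj - h : cj + h + 1] &= ~kernel.footprint
    return mask


def simulate_decimated_csr(
    shape: tuple[int, int],
    density: float,
    spec: DecimationSpec,
    seed: int = 0,
) -> GrayField:
    """CSR on a decimated study region: holes are cut first, then
    particles are placed uniformly over the remaining pixels (intensity 0
    and zero study area inside the holes)."""
    rng = np.random.default_rng(seed)
    mask = decimated_mask(shape, spec, rng)
    n = int(round(density * mask.sum()))
    if n < 2:
        raise DomainError("fewer than two particles requested")
    return GrayField(csr_intensities(mask, n, rng), mask=mask)
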