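"""Reading and writing fields, masks, profiles and references.

Images are 8-bit grayscale TIFF (single- or multi-page) or PNG; masks are
8-bit PNG/TIFF with 0 = outside.  Tabular outputs are plain CSV
(comma-separated, '.' decimal, header row, UTF-8); references carry full
provenance as JSON.  No reader or writer rescales intensities: K~ is not
invariant under intensity rescaling, so any contrast change must be an
explicit caller decision.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .field import GrayField
from .kfunction import CSRReference, KProfile

MASK_POLICIES = ("full", "nonzero", "file")


def _to_field(arr: np.ndarray, mask_policy: str, mask: np.ndarray | None,
              allow_conversion: bool) -> GrayField:
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        raise ValueError("color images are not supported; convert to grayscale first")
    if arr.dtype != np.uint8:
        if not allow_conversion:
            raise ValueError(
                f"expected 8-bit data, got {arr.dtype}; images being compared "
                "must share a bit depth — pass allow_conversion=True to "
                "right-shift 16-bit data to 8-bit explicitly"
            )
        if arr.dtype == np.uint16:
            arr = (arr >> 8).astype(np.uint8)
        else:
            raise ValueError(f"cannot convert dtype {arr.dtype} to 8-bit")
    if mask_policy == "full":
        m = np.ones(arr.shape, dtype=bool)
    elif mask_policy == "nonzero":
        m = arr > 0
    elif mask_policy == "file":
        if mask is None:
            raise ValueError("mask_policy='file' requires a mask array/path")
        m = np.asarray(mask) > 0
    else:
        raise ValueError(f"mask_policy must be one of {MASK_POLICIES}")
    return GrayField(arr.astype(np.int64), mask=m)


def read_gray_image(
    path: str | Path,
    mask_policy: str = "full",
    mask_path: str | Path | None = None,
    allow_conversion: bool = False,
) -> GrayField | list[GrayField]:
    """Read an 8-bit grayscale image as a particle field.

    Multi-page TIFFs return one field per page, in page order.  The mask
    policy is ``"full"`` (whole lattice is the study region),
    ``"nonzero"`` (study region = nonzero pixels, for pre-thresholded
    images where zero marks background) or ``"file"`` (explicit mask
    image, nonzero = inside).
    """
    path = Path(path)
    mask = None
    if mask_path is not None:
        mask = read_mask(mask_path)
        mask_policy = "file"
    if path.suffix.lower() in (".tif", ".tiff"):
        pages = tifffile.imread(path)
        if pages.ndim == 3 and pages.shape[-1] not in (3, 4):
            return [
                _to_field(p, mask_policy, mask, allow_conversion) for p in pages
            ]
        return _to_field(pages, mask_policy, mask, allow_conversion)
    arr = iio.imread(path)
    return _to_field(np.asarray(arr), mask_policy, mask, allow_conversion)


def read_mask(path: str | Path) -> np.ndarray:
    """Read a mask image; nonzero pixels are inside the study region."""
    return np.asarray(iio.imread(path)) > 0


def write_field(field: GrayField, path: str | Path) -> None:
    """Write intensities as 8-bit grayscale (TIFF or PNG by extension)."""
    path = Path(path)
    arr = field.masked_intensities.astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)


def write_stack(fields: list[GrayField], path: str | Path) -> None:
    """Write a list of fields as a multi-page 8-bit TIFF."""
    tifffile.imwrite(
        Path(path),
        np.stack([f.masked_intensities.astype(np.uint8) for f in fields]),
        photometric="minisblack",
    )


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean mask as an 8-bit image (255 = inside)."""
    arr = (np.asarray(mask, dtype=bool) * np.uint8(255))
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)


def profile_to_csv(
    profile: KProfile,
    path: str | Path,
    references: list[CSRReference] | None = None,
) -> None:
    """Write a K profile (with critical quantiles when references are
    given) as CSV with columns radius, k, ktilde, q01_emp, q99_emp,
    q01_cf, q99_cf."""
    profile.to_frame(references).to_csv(path, index=False)


def profile_from_csv(path: str | Path, n: int = 0, omega_area: int = 0,
                     edge_method: str = "full_field") -> KProfile:
    """Read back a profile CSV written by :func:`profile_to_csv`."""
    df = pd.read_csv(path)
    return KProfile(
        radii=df["radius"].to_numpy(dtype=float),
        k_values=df["k"].to_numpy(dtype=float),
        ktilde_values=df["ktilde"].to_numpy(dtype=float),
        n=n,
        omega_area=omega_area,
        edge_method=edge_method,
    )


def reference_to_json(reference: CSRReference, path: str | Path) -> None:
    """Serialize a CSR reference with full provenance (seed, replicates,
    method, mask hash)."""
    Path(path).write_text(
        json.dumps(dataclasses.asdict(reference), indent=2, sort_keys=True)
    )


def reference_from_json(path: str | Path) -> CSRReference:
    return CSRReference(**json.loads(Path(path).read_text()))
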