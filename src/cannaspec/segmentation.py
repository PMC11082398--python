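"""Plant/background segmentation and patch-spectrum extraction.

Background removal uses a normalized band difference (NBD), an NDVI-style
index computed from reflectance at 764.74 nm and 684.69 nm:

    NBD = (R_764.74 - R_684.69) / (R_764.74 + R_684.69)

Pixels with NBD strictly above 0.3 form the region of interest (ROI).
Non-overlapping 20 x 20 pixel patches covering strictly more than 70 % of
their area with ROI pixels are placed greedily in raster order; each patch
contributes one mean spectrum (averaged over its ROI pixels only) to the
feature table used for model development.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cannaspec.cube_io import HyperspectralCube, nearest_band

__all__ = [
    "NBD_BAND_A_NM",
    "NBD_BAND_B_NM",
    "NBD_THRESHOLD",
    "PATCH_SIZE",
    "MIN_COVERAGE",
    "NBDImage",
    "PatchSet",
    "compute_nbd",
    "threshold_roi",
    "extract_patches",
    "patch_mean_spectra",
    "spectrum_columns",
]

NBD_BAND_A_NM = 764.74   # near-infrared band
NBD_BAND_B_NM = 684.69   # red band
NBD_THRESHOLD = 0.3
PATCH_SIZE = 20
MIN_COVERAGE = 0.7


@dataclass
class NBDImage:
    """Per-pixel NBD values plus a validity flag.

    ``valid`` is false where the denominator R_a + R_b is zero; such pixels
    carry an NBD of NaN and can never enter the ROI.
    """

    values: np.ndarray
    valid: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]


@dataclass
class PatchSet:
    """Accepted patch corners (upper-left, row-major order) with coverages."""

    corners: list[tuple[int, int]]
    size: int = PATCH_SIZE
    coverages: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.corners)


def compute_nbd(
    cube: HyperspectralCube,
    band_a_nm: float = NBD_BAND_A_NM,
    band_b_nm: float = NBD_BAND_B_NM,
) -> NBDImage:
    """Normalized band difference (R_a - R_b)/(R_a + R_b) per pixel.

    Zero-denominator pixels are flagged invalid (NaN value) so downstream
    thresholding treats them as background.
    """
    ia = nearest_band(cube, band_a_nm)
    ib = nearest_band(cube, band_b_nm)
    ra = cube.reflectance[:, :, ia]
    rb = cube.reflectance[:, :, ib]
    denom = ra + rb
    valid = denom != 0
    values = np.full(ra.shape, np.nan)
    np.divide(ra - rb, denom, out=values, where=valid)
    return NBDImage(values=values, valid=valid)


def threshold_roi(nbd: NBDImage, threshold: float = NBD_THRESHOLD) -> np.ndarray:
    """Boolean ROI mask: NBD strictly greater than ``threshold``.

    Invalid (zero-denominator) pixels are never part of the ROI.
    """
    if not -1.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (-1, 1); got {threshold}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # NaN comparisons
        mask = (nbd.values > threshold) & nbd.valid
    return mask


def extract_patches(
    mask: np.ndarray,
    size: int = PATCH_SIZE,
    min_coverage: float = MIN_COVERAGE,
) -> PatchSet:
    """Greedy raster-order placement of non-overlapping square patches.

    Candidate corners are scanned top-to-bottom, left-to-right with stride 1.
    A candidate is accepted when (a) strictly more than ``min_coverage`` of
    its ``size x size`` pixels are ROI pixels and (b) it does not overlap any
    previously accepted patch.  The scan order makes the placement
    deterministic for a given mask.
    """
    mask = np.asarray(mask, dtype=bool)
    rows, cols = mask.shape
    if size > rows or size > cols:
        warnings.warn(
            f"patch size {size} exceeds image shape {mask.shape}; returning empty set",
            stacklevel=2,
        )
        return PatchSet(corners=[], size=size, coverages=[])

    area = size * size
    # summed-area table for O(1) coverage queries
    sat = np.zeros((rows + 1, cols + 1), dtype=np.int64)
    np.cumsum(np.cumsum(mask, axis=0), axis=1, out=sat[1:, 1:])
    counts = (
        sat[size:, size:]
        - sat[:-size, size:]
        - sat[size:, :-size]
        + sat[:-size, :-size]
    )
    # divide rather than multiply so an exactly-70% patch (280/400) compares
    # equal to the threshold and is rejected by the strict inequality
    candidate_rows, candidate_cols = np.nonzero(counts / area > min_coverage)

    occupied = np.zeros((rows, cols), dtype=bool)
    corners: list[tuple[int, int]] = []
    coverages: list[float] = []
    for r, c in zip(candidate_rows.tolist(), candidate_cols.tolist()):
        if occupied[r: r + size, c: c + size].any():
            continue
        occupied[r: r + size, c: c + size] = True
        corners.append((r, c))
        coverages.append(counts[r, c] / area)
    return PatchSet(corners=corners, size=size, coverages=coverages)


def spectrum_columns(n_bands: int) -> list[str]:
    """Column names used for the spectral part of a spectrum table."""
    return [f"b{i:03d}" for i in range(n_bands)]


def patch_mean_spectra(
    cube: HyperspectralCube,
    patches: PatchSet,
    mask: np.ndarray,
) -> pd.DataFrame:
    """Mean spectrum over the ROI pixels of each patch.

    Returns a spectrum table: one row per patch with provenance columns
    (``cube_id``, ``sample_id``, ``drying_method``, ``day``, ``patch_row``,
    ``patch_col``) followed by one reflectance column per band.  Background
    pixels inside a patch are excluded from the average so that patch
    spectra are not diluted by non-plant material.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != cube.shape[:2]:
        raise ValueError("mask shape does not match cube spatial shape")
    size = patches.size
    meta = cube.metadata
    rows = []
    spectra = np.empty((len(patches), cube.n_bands))
    for i, (r, c) in enumerate(patches.corners):
        sub_mask = mask[r: r + size, c: c + size]
        n_roi = int(sub_mask.sum())
        if n_roi == 0:
            raise ValueError(f"patch at ({r}, {c}) contains no ROI pixels")
        sub = cube.reflectance[r: r + size, c: c + size, :]
        spectra[i] = sub[sub_mask].mean(axis=0)
        rows.append(
            {
                "cube_id": meta.get("cube_id", ""),
                "sample_id": meta.get("sample_id", ""),
                "drying_method": meta.get("drying_method", ""),
                "day": meta.get("day", np.nan),
                "patch_row": r,
                "patch_col": c,
            }
        )
    table = pd.DataFrame(rows, columns=["cube_id", "sample_id", "drying_method", "day", "patch_row", "patch_col"])
    spec_df = pd.DataFrame(spectra, columns=spectrum_columns(cube.n_bands))
    return pd.concat([table, spec_df], axis=1)
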