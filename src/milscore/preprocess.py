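"""Biopsy preprocessing: tissue segmentation, patch tiling, stain
normalization and patch quality control.

The pipeline mirrors standard whole-slide practice for H&E tissue on a
white slide: segment the tissue foreground, tile it into overlapping
fixed-size patches in raster order, normalise staining against a reference,
and reject patches with quality issues (background, too little tissue,
blur, artefacts), each rejection carrying exactly one reason — the first
failing check in the fixed order background -> low_tissue -> blur ->
artefact.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import color, filters, morphology

__all__ = [
    "TissueMask",
    "PatchRecord",
    "QCReason",
    "QCThresholds",
    "QCSummary",
    "StainReference",
    "segment_tissue",
    "tile_patches",
    "fit_stain_reference",
    "normalize_stain",
    "qc_filter",
]

#: a pixel is "near-white" (slide background / blank artefact) when every
#: channel is at or above this 8-bit value
WHITE_THRESHOLD = 220

#: a pixel is "very dark" (fold artefact) below this luminance
DARK_LUMINANCE = 80.0


@dataclass(frozen=True)
class TissueMask:
    mask: np.ndarray

    @property
    def tissue_fraction(self) -> float:
        return float(self.mask.mean())


def _check_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3 or image.size == 0:
        raise ValueError("expected a non-empty RGB (H, W, 3) image")
    return image


def segment_tissue(
    image: np.ndarray,
    min_hole_area: int | None = None,
    min_object_area: int | None = None,
) -> TissueMask:
    """Separate tissue foreground from the white slide background.

    Thresholds the HSV saturation channel with Otsu's criterion, then
    applies morphological closing and hole filling.  Interior holes up to
    ``min_hole_area`` (default: the full image, i.e. all enclosed holes)
    are filled — blank/streak artefacts planted inside tissue therefore
    stay part of the mask, which is what lets QC tell them apart from real
    background.  Degenerate images (all background or all tissue) are
    handled by an absolute saturation floor instead of Otsu.
    """
    image = _check_rgb(image)
    sat = color.rgb2hsv(image)[..., 1]
    near_white = (image >= WHITE_THRESHOLD).all(axis=2)
    if near_white.all():
        return TissueMask(np.zeros(sat.shape, dtype=bool))
    # Otsu needs both modes present; fall back to an absolute floor when
    # the image is (almost) entirely tissue or entirely background
    if near_white.mean() < 0.01 or sat.std() < 0.01:
        mask = sat > 0.06
    else:
        thr = filters.threshold_otsu(sat)
        mask = sat > min(thr, 0.12)
    mask &= ~near_white
    # close on an edge-replicated pad so border tissue is not eroded away
    pad = 4
    padded = np.pad(mask, pad, mode="edge")
    padded = ndimage.binary_closing(padded, structure=morphology.disk(3))
    mask = padded[pad:-pad, pad:-pad]
    if min_hole_area is None:
        mask = ndimage.binary_fill_holes(mask)
    else:
        mask = morphology.remove_small_holes(mask, area_threshold=min_hole_area)
    if min_object_area is None:
        min_object_area = max(16, mask.size // 4096)
    labels, n = ndimage.label(mask)
    if n:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        small = np.flatnonzero(sizes < min_object_area) + 1
        if small.size:
            mask &= ~np.isin(labels, small)
    return TissueMask(mask)


class QCReason(str, enum.Enum):
    BACKGROUND = "background"
    LOW_TISSUE = "low_tissue"
    BLUR = "blur"
    ARTEFACT = "artefact"


@dataclass
class PatchRecord:
    """One tiled patch: window coordinates, pixels, and QC status.

    Windows are 0-based, (row, col), half-open:
    ``[row0, row0 + size) x [col0, col0 + size)``.
    """

    biopsy_id: str
    row0: int
    col0: int
    size: int
    pixels: np.ndarray
    tissue_fraction: float
    qc_status: str = "kept"
    qc_reason: QCReason | None = None


def tile_patches(
    image: np.ndarray,
    mask: TissueMask,
    patch_size: int = 224,
    stride: int = 112,
    min_tissue: float = 0.3,
    biopsy_id: str = "",
) -> list[PatchRecord]:
    """Tile an image into overlapping patches in raster order.

    Grid positions per axis number ``floor((dim - patch_size)/stride) + 1``;
    only fully-inside windows are emitted, and only those whose tissue
    fraction (from ``mask``) reaches ``min_tissue``.  ``stride <
    patch_size`` yields overlapping patches.
    """
    image = _check_rgb(image)
    h, w = image.shape[:2]
    if mask.mask.shape != (h, w):
        raise ValueError("mask dimensions must equal image dimensions")
    if not 0 < stride <= patch_size:
        raise ValueError("require 0 < stride <= patch_size")
    if patch_size > min(h, w):
        raise ValueError("patch_size larger than image")
    # summed-area table makes per-window tissue fractions O(1)
    integral = np.pad(mask.mask.astype(np.int64), ((1, 0), (1, 0))).cumsum(0).cumsum(1)
    records: list[PatchRecord] = []
    for r0 in range(0, h - patch_size + 1, stride):
        for c0 in range(0, w - patch_size + 1, stride):
            r1, c1 = r0 + patch_size, c0 + patch_size
            tissue = (
                integral[r1, c1] - integral[r0, c1] - integral[r1, c0] + integral[r0, c0]
            ) / (patch_size * patch_size)
            if tissue >= min_tissue:
                records.append(
                    PatchRecord(
                        biopsy_id=biopsy_id,
                        row0=r0,
                        col0=c0,
                        size=patch_size,
                        pixels=image[r0:r1, c0:c1],
                        tissue_fraction=float(tissue),
                    )
                )
    return records


@dataclass(frozen=True)
class StainReference:
    """Target per-channel LAB statistics for Reinhard colour transfer."""

    mean: np.ndarray  # (3,) LAB
    std: np.ndarray  # (3,) LAB

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float)
        std = np.asarray(self.std, dtype=float)
        if mean.shape != (3,) or std.shape != (3,):
            raise ValueError("reference statistics must be length-3 per channel")
        if (std <= 0).any():
            raise ValueError("reference dispersions must be positive")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "std", std)


def _foreground(image: np.ndarray) -> np.ndarray:
    return ~(image >= WHITE_THRESHOLD).all(axis=2)


def fit_stain_reference(images: Sequence[np.ndarray] | np.ndarray) -> StainReference:
    """Pool non-background LAB statistics over one or more RGB images."""
    if isinstance(images, np.ndarray) and images.ndim == 3:
        images = [images]
    pixels = []
    for image in images:
        image = _check_rgb(image)
        fg = _foreground(image)
        if fg.any():
            pixels.append(color.rgb2lab(image)[fg])
    if not pixels:
        raise ValueError("no foreground pixels to build a stain reference from")
    pooled = np.concatenate(pixels, axis=0)
    std = pooled.std(axis=0)
    std[std <= 1e-8] = 1e-8
    return StainReference(mean=pooled.mean(axis=0), std=std)


def normalize_stain(
    patch: np.ndarray,
    reference: StainReference,
    method: str = "reinhard",
) -> tuple[np.ndarray, bool]:
    """Match a patch's colour statistics to a stain reference.

    ``reinhard`` (default) standardises per-channel LAB statistics of the
    non-background pixels to the reference; background (near-white) pixels
    are excluded from estimation and left untouched.  ``macenko`` estimates
    a two-stain basis from the optical-density cloud by SVD and rescales
    stain concentrations — exposed for completeness; Reinhard is what the
    QC and acceptance checks use.

    Returns ``(normalized_patch, degenerate_flag)``: degenerate patches
    (no foreground, or zero dispersion) come back unchanged with the flag
    set.
    """
    patch = _check_rgb(patch)
    fg = _foreground(patch)
    if fg.sum() < 16:
        warnings.warn("degenerate patch: no foreground to normalise", stacklevel=2)
        return patch.copy(), True
    if method == "reinhard":
        lab = color.rgb2lab(patch)
        mean, std = lab[fg].mean(axis=0), lab[fg].std(axis=0)
        if (std <= 1e-8).any():
            warnings.warn("degenerate patch: zero colour dispersion", stacklevel=2)
            return patch.copy(), True
        lab[fg] = (lab[fg] - mean) / std * reference.std + reference.mean
        out = color.lab2rgb(lab)
        out = np.clip(np.rint(out * 255.0), 0, 255).astype(np.uint8)
        out[~fg] = patch[~fg]
        return out, False
    if method == "macenko":
        return _normalize_macenko(patch, fg)
    raise ValueError(f"unknown stain normalization method {method!r}")


#: canonical H&E stain optical-density basis (haematoxylin, eosin)
_HE_REFERENCE = np.array([[0.65, 0.70, 0.29], [0.07, 0.99, 0.11]])


def _normalize_macenko(patch: np.ndarray, fg: np.ndarray) -> tuple[np.ndarray, bool]:
    od = -np.log(np.clip(patch[fg].astype(float), 1, 255) / 255.0)
    od = od[(od > 0.05).any(axis=1)]
    if od.shape[0] < 32:
        warnings.warn("degenerate patch: too little stained tissue", stacklevel=2)
        return patch.copy(), True
    _, _, vt = np.linalg.svd(od - od.mean(axis=0), full_matrices=False)
    plane = vt[:2]
    proj = od @ plane.T
    phi = np.arctan2(proj[:, 1], proj[:, 0])
    lo, hi = np.percentile(phi, [1, 99])
    v1 = plane.T @ np.array([np.cos(lo), np.sin(lo)])
    v2 = plane.T @ np.array([np.cos(hi), np.sin(hi)])
    stains = np.stack([np.sign(v) * v for v in (v1, v2)])
    stains /= np.linalg.norm(stains, axis=1, keepdims=True)
    if stains[0, 0] < stains[1, 0]:  # haematoxylin has the larger red OD
        stains = stains[::-1]
    od_full = -np.log(np.clip(patch.reshape(-1, 3).astype(float), 1, 255) / 255.0)
    conc, *_ = np.linalg.lstsq(stains.T, od_full.T, rcond=None)
    conc = np.clip(conc, 0, None)
    scale = np.percentile(conc, 99, axis=1)
    scale[scale <= 1e-8] = 1e-8
    target = np.array([1.0, 1.0])
    conc = conc * (target / scale)[:, None]
    out = 255.0 * np.exp(-(_HE_REFERENCE.T @ conc))
    out = np.clip(np.rint(out.T.reshape(patch.shape)), 0, 255).astype(np.uint8)
    out[~fg] = patch[~fg]
    return out, False


@dataclass(frozen=True)
class QCThresholds:
    """Rejection thresholds, calibrated on the synthetic generator's output.

    ``max_background``: near-white fraction above which a patch is slide
    background.  ``min_tissue``: tissue-mask fraction floor.  ``blur_*``:
    a patch is blurred when at least ``blur_cell_fraction`` of its
    ``blur_grid``^2 cells (those at least half tissue) fall below
    ``blur_cell_var`` Laplacian variance — cell-wise scoring catches
    half-blurred patches that still contain sharp texture elsewhere.
    ``artefact_*``: excess near-white *inside* the tissue mask (blank /
    shear streaks) or very-dark fraction (folds).
    """

    max_background: float = 0.75
    min_tissue: float = 0.3
    blur_cell_var: float = 25.0
    blur_cell_fraction: float = 0.45
    blur_grid: int = 14
    artefact_white_excess: float = 0.25
    artefact_dark_fraction: float = 0.12
    #: combined anomalous-area fraction (white-in-tissue + very dark +
    #: flat-texture tissue cells); catches mixed artefacts none of which
    #: dominates alone
    artefact_combined: float = 0.28


@dataclass
class QCSummary:
    total: int = 0
    kept: int = 0
    rejected: dict = field(default_factory=dict)


def _blur_fraction(patch: np.ndarray, mask_crop: np.ndarray, grid: int, var_thr: float) -> float:
    grey = patch.mean(axis=2)
    lap = ndimage.laplace(grey)
    n = patch.shape[0]
    cell = max(1, n // grid)
    flagged = total = 0
    for r in range(0, n - cell + 1, cell):
        for c in range(0, n - cell + 1, cell):
            if mask_crop[r : r + cell, c : c + cell].mean() >= 0.5:
                total += 1
                if lap[r : r + cell, c : c + cell].var() < var_thr:
                    flagged += 1
    return flagged / total if total else 0.0


def qc_filter(
    patches: Sequence[PatchRecord],
    thresholds: QCThresholds | None = None,
    tissue_mask: TissueMask | None = None,
) -> tuple[list[PatchRecord], list[PatchRecord], QCSummary]:
    """Partition patches into kept and rejected-with-reason.

    Checks run in the fixed order background -> low_tissue -> blur ->
    artefact and the first failure is the recorded reason, so reporting is
    reproducible.  ``tissue_mask`` (the biopsy-level segmentation) refines
    the blur and artefact checks; without it the patch is treated as fully
    tissue for those checks.  kept + rejected always partitions the input.
    """
    thresholds = thresholds or QCThresholds()
    if len({p.biopsy_id for p in patches}) > 1:
        raise ValueError("qc_filter expects patches from a single biopsy")
    kept: list[PatchRecord] = []
    rejected: list[PatchRecord] = []
    summary = QCSummary(total=len(patches), rejected={r.value: 0 for r in QCReason})
    for p in patches:
        white = (p.pixels >= WHITE_THRESHOLD).all(axis=2)
        if tissue_mask is not None:
            crop = tissue_mask.mask[p.row0 : p.row0 + p.size, p.col0 : p.col0 + p.size]
        else:
            crop = np.ones((p.size, p.size), dtype=bool)
        reason: QCReason | None = None
        if white.mean() > thresholds.max_background:
            reason = QCReason.BACKGROUND
        elif p.tissue_fraction < thresholds.min_tissue:
            reason = QCReason.LOW_TISSUE
        else:
            blur_frac = _blur_fraction(
                p.pixels, crop, thresholds.blur_grid, thresholds.blur_cell_var
            )
            if blur_frac >= thresholds.blur_cell_fraction:
                reason = QCReason.BLUR
            else:
                lum = p.pixels.astype(float) @ np.array([0.3, 0.59, 0.11])
                white_in_tissue = float((white & crop).mean())
                dark = float((lum < DARK_LUMINANCE).mean())
                tissue_frac = max(float(crop.mean()), 1e-9)
                combined = white_in_tissue + dark + blur_frac * tissue_frac
                if (
                    white_in_tissue > thresholds.artefact_white_excess
                    or dark > thresholds.artefact_dark_fraction
                    or combined >= thresholds.artefact_combined
                ):
                    reason = QCReason.ARTEFACT
        if reason is None:
            kept.append(replace(p, qc_status="kept", qc_reason=None))
            summary.kept += 1
        else:
            rejected.append(replace(p, qc_status="rejected", qc_reason=reason))
            summary.rejected[reason.value] += 1
    return kept, rejected, summary
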