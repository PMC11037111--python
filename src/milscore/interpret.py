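"""Attention heatmaps: red/yellow/green patch-relevance overlays.

The attention weights of a MIL model rank the patches of a biopsy by their
contribution to the severity call.  Patches are classed by rank tercile —
top third red (most relevant), middle yellow, bottom green — and painted
over the source image; where overlapping patches cover a pixel, their mean
attention weight decides the pixel's colour class.  Rejected patches stay
uncoloured.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .mil import AttentionOutput
from .preprocess import PatchRecord

__all__ = ["Heatmap", "render_heatmap", "top_patches", "RELEVANCE_COLORS"]

RELEVANCE_COLORS = {
    "red": np.array([220, 40, 40], dtype=float),
    "yellow": np.array([235, 200, 40], dtype=float),
    "green": np.array([60, 170, 60], dtype=float),
}


@dataclass
class Heatmap:
    overlay: np.ndarray  # (H, W, 3) uint8
    patch_classes: list[str]  # per kept patch, aligned to input order
    patch_weights: np.ndarray  # (N,)


def _tercile_classes(weights: np.ndarray) -> tuple[list[str], dict[str, float]]:
    """Rank-tercile relevance class per patch plus weight boundaries.

    Classes are assigned on rank, not weight value, so heavily skewed
    attention distributions still produce three classes.  Sorting is
    stable on (descending weight, input order); the all-ties degenerate
    case maps every patch to yellow.
    """
    n = weights.shape[0]
    if np.allclose(weights, weights[0]):
        return ["yellow"] * n, {"red_min": np.inf, "yellow_min": -np.inf}
    order = np.lexsort((np.arange(n), -weights))
    chunks = np.array_split(order, 3)
    classes = [""] * n
    for name, chunk in zip(("red", "yellow", "green"), chunks):
        for idx in chunk:
            classes[idx] = name
    bounds = {
        "red_min": float(weights[chunks[0]].min()) if chunks[0].size else np.inf,
        "yellow_min": float(weights[chunks[1]].min()) if chunks[1].size else -np.inf,
    }
    return classes, bounds


def render_heatmap(
    image: np.ndarray,
    patches: list[PatchRecord],
    attention: AttentionOutput,
    alpha: float = 0.4,
) -> Heatmap:
    """Overlay rank-tercile attention colours on a biopsy image.

    ``patches`` are the kept patches the attention weights refer to, in
    order.  Overlapping windows are blended by the per-pixel mean of the
    covering patches' weights before the pixel is classified against the
    tercile weight boundaries; output dimensions equal the input's.
    """
    image = np.asarray(image)
    a = np.asarray(attention.a, dtype=float)
    if len(patches) != a.shape[0]:
        raise ValueError(
            f"attention length {a.shape[0]} != kept patch count {len(patches)}"
        )
    classes, bounds = _tercile_classes(a)
    h, w = image.shape[:2]
    wsum = np.zeros((h, w))
    cover = np.zeros((h, w))
    for p, weight in zip(patches, a):
        wsum[p.row0 : p.row0 + p.size, p.col0 : p.col0 + p.size] += weight
        cover[p.row0 : p.row0 + p.size, p.col0 : p.col0 + p.size] += 1.0
    covered = cover > 0
    mean_w = np.zeros((h, w))
    mean_w[covered] = wsum[covered] / cover[covered]

    overlay = image.astype(float).copy()
    if np.isinf(bounds["red_min"]) and bounds["yellow_min"] == -np.inf:
        pixel_class = np.full((h, w), "yellow", dtype=object)
    else:
        pixel_class = np.where(
            mean_w >= bounds["red_min"],
            "red",
            np.where(mean_w >= bounds["yellow_min"], "yellow", "green"),
        ).astype(object)
    for name, colour in RELEVANCE_COLORS.items():
        sel = covered & (pixel_class == name)
        overlay[sel] = (1.0 - alpha) * overlay[sel] + alpha * colour
    return Heatmap(
        overlay=np.clip(np.rint(overlay), 0, 255).astype(np.uint8),
        patch_classes=classes,
        patch_weights=a,
    )


def top_patches(
    attention: AttentionOutput, patches: list[PatchRecord], k: int
) -> list[tuple[PatchRecord, float]]:
    """The k highest-attention patches, descending, raster-stable ties.

    Asking for more patches than exist returns them all with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    a = np.asarray(attention.a, dtype=float)
    if len(patches) != a.shape[0]:
        raise ValueError("attention length != patch count")
    if k > a.shape[0]:
        warnings.warn(
            f"requested k={k} > {a.shape[0]} patches; returning all", stacklevel=2
        )
        k = a.shape[0]
    order = np.lexsort((np.arange(a.shape[0]), -a))[:k]
    return [(patches[i], float(a[i])) for i in order]
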