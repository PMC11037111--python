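"""Synthetic H&E-like biopsy generator with planted, mask-level ground truth.

Real IBD trial slides are not publicly available, so every downstream stage
(segmentation, tiling, QC, stain normalization, MIL training, attention
heatmaps) is exercised on generated biopsies whose pathology is *planted*
and therefore exactly known:

* biopsy-shaped tissue on a white slide background, with crypt-like
  low-frequency texture and fine nuclear speckle;
* per-subgrade pathology features — neutrophil-like dark-purple dots in the
  epithelial band (PolysEP / Geboes G3) or the lamina propria (PolysLP /
  G2B), a diffuse mononuclear-infiltrate density field (MonosLP / G1),
  contiguous pale disrupted regions at the epithelial border (EPDAM / G5),
  ulcer-like craters (ULCER), crypt-destruction patches (G4), eosinophil-red
  dots (G2A) and mild architectural distortion (G0);
* per-channel multiplicative stain jitter in optical-density (log-RGB)
  space, so white background is invariant and stain normalization has a
  measurable batch effect to remove;
* planted artefacts (blank-out, blur, shear streaks, tissue folds) painted
  last over their own mask, giving QC a pixel-level oracle.

Feature placement is severity-nested: for a fixed seed, severity *s* plants
a prefix of the candidate set used at severity *s+1*, so planted area is
non-decreasing (dot counts strictly increasing) in severity.  All randomness
flows from per-component child generators of one integer seed, making the
output byte-identical across calls.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import draw, transform

from .scoring import (
    SEVERITY_MAX,
    Compartment,
    ScoreSet,
    ScoringError,
    System,
    subgrades_for,
)

__all__ = [
    "SyntheticSpec",
    "SyntheticTruth",
    "DatasetResult",
    "ARTEFACT_TYPES",
    "generate_biopsy",
    "generate_dataset",
    "sample_stain_factors",
    "apply_stain_jitter",
]

ARTEFACT_TYPES = ("blank", "blur", "shear_streak", "fold")


def sample_stain_factors(rng: np.random.Generator, jitter: float) -> np.ndarray:
    """Per-channel optical-density factors drawn from [1 - jitter, 1 + jitter]."""
    return rng.uniform(1.0 - jitter, 1.0 + jitter, size=3)


def apply_stain_jitter(image: np.ndarray, factors: np.ndarray) -> np.ndarray:
    """Scale each channel's optical density: ``I' = 255 (I/255)^f``.

    Multiplicative in log-RGB (Beer-Lambert) space, so pure white — zero
    optical density — is invariant and only stained tissue shifts.
    Preserves the input dtype (uint8 in, uint8 out).
    """
    factors = np.asarray(factors, dtype=float)
    out = 255.0 * (np.clip(image, 1.0, 255.0) / 255.0) ** factors[None, None, :]
    if np.issubdtype(np.asarray(image).dtype, np.integer):
        return np.clip(np.rint(out), 0, 255).astype(np.uint8)
    return out

# painter kind per (system, subgrade)
_FEATURE_KIND: dict[System, dict[str, str]] = {
    System.GHAS: {
        "EPDAM": "damage_band",
        "PolysEP": "dots_epithelium",
        "PolysLP": "dots_lamina",
        "MonosLP": "diffuse",
        "ULCER": "crater",
    },
    System.GEBOES: {
        "G0": "diffuse_mild",
        "G1": "diffuse",
        "G2A": "dots_eosinophil",
        "G2B": "dots_lamina",
        "G3": "dots_epithelium",
        "G4": "pale_patches",
        "G5": "damage_band",
    },
}

_COL_BASE = np.array([216.0, 166.0, 192.0])
_COL_TEXTURE = np.array([150.0, 110.0, 160.0])
_COL_NUCLEI = np.array([120.0, 90.0, 150.0])
_COL_DIFFUSE = np.array([135.0, 95.0, 155.0])
_COL_MILD = np.array([150.0, 120.0, 165.0])
_COL_DAMAGE = np.array([212.0, 192.0, 200.0])
_COL_CRATER = np.array([206.0, 188.0, 194.0])
_COL_PALE = np.array([210.0, 195.0, 202.0])
_COL_NEUTROPHIL = np.array([64.0, 34.0, 104.0])
_COL_EOSINOPHIL = np.array([196.0, 84.0, 92.0])

#: tissue pixels are clipped below this value pre-jitter so that only
#: slide background and planted artefacts can ever look near-white
_TISSUE_MAX = 215.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic biopsy.

    ``subgrade_severities`` uses the subgrade names of ``system``; missing
    subgrades default to severity 0.  ``stain_jitter`` is the half-width of
    the per-channel multiplicative optical-density factor range
    (0.2 -> factors drawn in [0.8, 1.2]).  ``artefact_fraction`` is the
    target artefact area as a proportion of tissue area, split evenly over
    ``artefact_types``.
    """

    image_size: int = 1024
    system: System = System.GHAS
    compartment: Compartment = Compartment.COLON
    subgrade_severities: Mapping[str, int] = field(default_factory=dict)
    stain_jitter: float = 0.2
    artefact_types: tuple[str, ...] = ()
    artefact_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "system", System(self.system))
        object.__setattr__(self, "compartment", Compartment(self.compartment))
        if self.image_size < 64:
            raise ValueError("image_size must be >= 64")
        if not 0.0 <= self.artefact_fraction <= 1.0:
            raise ValueError("artefact_fraction must lie in [0, 1]")
        if not 0.0 <= self.stain_jitter < 1.0:
            raise ValueError("stain_jitter must lie in [0, 1)")
        bad = set(self.artefact_types) - set(ARTEFACT_TYPES)
        if bad:
            raise ValueError(f"unknown artefact type(s) {sorted(bad)}")
        object.__setattr__(self, "artefact_types", tuple(self.artefact_types))
        # validates subgrade names, severity ranges and compartment rules
        score = ScoreSet(
            system=self.system,
            compartment=self.compartment,
            severities=dict(self.subgrade_severities),
        )
        object.__setattr__(self, "subgrade_severities", dict(score.severities))

    @property
    def score(self) -> ScoreSet:
        return ScoreSet(
            system=self.system,
            compartment=self.compartment,
            severities=self.subgrade_severities,
        )


@dataclass
class SyntheticTruth:
    """Planted-feature ground truth for one generated biopsy."""

    tissue_mask: np.ndarray
    feature_masks: dict[str, np.ndarray]
    artefact_mask: np.ndarray
    score: ScoreSet


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, stream]))


def _smooth_field(rng: np.random.Generator, size: int, grid: int, sigma: float) -> np.ndarray:
    """Low-frequency noise field in [-1, 1]-ish range, generated coarse then upsampled."""
    coarse = rng.standard_normal((grid, grid))
    coarse = ndimage.gaussian_filter(coarse, sigma)
    fine = transform.resize(coarse, (size, size), order=1, anti_aliasing=False)
    scale = np.abs(fine).max()
    return fine / scale if scale > 0 else fine


def _tissue_mask(rng: np.random.Generator, size: int) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    cy = size * (0.5 + 0.05 * rng.uniform(-1, 1))
    cx = size * (0.5 + 0.05 * rng.uniform(-1, 1))
    theta = rng.uniform(0, np.pi)
    ry = size * rng.uniform(0.30, 0.40)
    rx = size * rng.uniform(0.36, 0.46)
    y, x = yy - cy, xx - cx
    u = (x * np.cos(theta) + y * np.sin(theta)) / rx
    v = (-x * np.sin(theta) + y * np.cos(theta)) / ry
    bump = 1.0 - np.sqrt(u * u + v * v)
    noise = _smooth_field(rng, size, max(16, size // 32), 2.5)
    mask = (bump + 0.30 * noise) > 0
    mask = ndimage.binary_closing(mask, structure=np.ones((5, 5)))
    mask = ndimage.binary_fill_holes(mask)
    # keep the largest connected component only
    labels, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    return mask


def _sample_points_in(
    rng: np.random.Generator,
    region: np.ndarray,
    count: int,
    min_dist: float,
) -> list[tuple[int, int]]:
    """Greedy Poisson-disk-like sampling restricted to a boolean region.

    Candidates are drawn from one sequential stream and accepted in order,
    so the accepted list for a smaller ``count`` is a prefix of the list
    for a larger one (severity nesting).
    """
    idx = np.flatnonzero(region)
    if idx.size == 0:
        return []
    w = region.shape[1]
    accepted: list[tuple[int, int]] = []
    attempts = 0
    max_attempts = count * 60 + 200
    while len(accepted) < count and attempts < max_attempts:
        attempts += 1
        flat = int(idx[rng.integers(idx.size)])
        r, c = divmod(flat, w)
        if all((r - ar) ** 2 + (c - ac) ** 2 >= min_dist**2 for ar, ac in accepted):
            accepted.append((r, c))
    return accepted


def _paint_dots(
    img: np.ndarray,
    mask: np.ndarray,
    rng: np.random.Generator,
    region: np.ndarray,
    count: int,
    color: np.ndarray,
    r_lo: float,
    r_hi: float,
    n_foci: int = 0,
) -> None:
    """Plant dot-like objects, optionally clustered into inflammatory foci.

    With ``n_foci > 0`` the dots are confined to disk-shaped foci sampled
    inside ``region`` — IBD neutrophil infiltration is focal rather than
    uniform, and clustering keeps planted pathology localised to a few
    patches, which is what attention heatmaps are expected to find.  The
    foci are drawn before the dots from the same stream, so severity only
    changes how many dots of a fixed candidate sequence are planted.
    """
    size = img.shape[0]
    if n_foci > 0:
        centres = _sample_points_in(rng, region, n_foci, min_dist=size / 3.5)
        if centres:
            radius = size / 7.0
            yy, xx = np.mgrid[0:size, 0:size].astype(float)
            focal = np.zeros((size, size), dtype=bool)
            for r, c in centres:
                focal |= (yy - r) ** 2 + (xx - c) ** 2 <= radius**2
            if (region & focal).any():
                region = region & focal
    pts = _sample_points_in(rng, region, count, min_dist=3.2 * r_hi)
    radii = rng.uniform(r_lo, r_hi, size=len(pts))
    for (r, c), rad in zip(pts, radii):
        rr, cc = draw.disk((r, c), rad, shape=(size, size))
        img[rr, cc] = color
        mask[rr, cc] = True


def _blob_region(
    rng: np.random.Generator,
    domain: np.ndarray,
    frac: float,
    size: int,
    sigma: float = 4.0,
) -> np.ndarray:
    """Blobby sub-region of ``domain`` covering ~``frac`` of the tissue area.

    Uses one smooth field with a quantile threshold, so a larger ``frac``
    (higher severity) yields a superset region for the same RNG stream.
    """
    if frac <= 0:
        return np.zeros_like(domain)
    fld = _smooth_field(rng, size, max(16, size // 16), sigma)
    vals = fld[domain]
    if vals.size == 0:
        return np.zeros_like(domain)
    frac = min(frac, 1.0)
    thr = np.quantile(vals, 1.0 - frac)
    return domain & (fld > thr)


def generate_biopsy(spec: SyntheticSpec) -> tuple[np.ndarray, SyntheticTruth]:
    """Render one synthetic biopsy and its planted ground truth.

    Returns an (H, W, 3) uint8 RGB image (white background outside tissue)
    and a :class:`SyntheticTruth` whose ``feature_masks`` hold one boolean
    mask per subgrade of the spec's scoring system (empty at severity 0).
    Deterministic for a fixed spec, including the seed.
    """
    size = spec.image_size
    seed = spec.seed
    tissue = _tissue_mask(_rng(seed, 0), size)
    tissue_area = int(tissue.sum())

    dist = ndimage.distance_transform_edt(tissue)
    band_depth = max(6.0, size / 24.0)
    epithelium = tissue & (dist <= band_depth)
    lamina = tissue & (dist > band_depth)
    if not lamina.any():  # degenerate thin tissue: fall back to whole tissue
        lamina = tissue

    img = np.full((size, size, 3), 255.0)
    # crypt-like low-frequency texture + fine nuclear speckle
    tex_rng = _rng(seed, 1)
    crypt = _smooth_field(tex_rng, size, max(32, size // 8), 2.0)
    fine = ndimage.gaussian_filter(tex_rng.standard_normal((size, size)), 1.1)
    fine = fine / max(np.abs(fine).max(), 1e-9)
    base = _COL_BASE + (crypt[..., None] * 0.5 + 0.5) * (_COL_TEXTURE - _COL_BASE) * 0.45
    img[tissue] = base[tissue]
    nuclei = tissue & (fine > np.quantile(fine[tissue], 0.82) if tissue.any() else False)
    img[nuclei] = 0.45 * img[nuclei] + 0.55 * _COL_NUCLEI
    # broadband speckle keeps Laplacian energy high everywhere in tissue
    speckle = fine[..., None] * 14.0
    img[tissue] += speckle[tissue]

    scale = (size / 1024.0) ** 2
    kinds = _FEATURE_KIND[spec.system]
    feature_masks: dict[str, np.ndarray] = {}
    for stream, name in enumerate(subgrades_for(spec.system)):
        sev = spec.subgrade_severities.get(name, 0)
        fmask = np.zeros((size, size), dtype=bool)
        rng = _rng(seed, 10 + stream)
        kind = kinds[name]
        if sev > 0:
            if kind == "dots_epithelium":
                n = max(3, round(30 * scale)) * sev
                _paint_dots(img, fmask, rng, epithelium, n, _COL_NEUTROPHIL, 2.0, 4.0, n_foci=1)
            elif kind == "dots_lamina":
                n = max(3, round(30 * scale)) * sev
                _paint_dots(img, fmask, rng, lamina, n, _COL_NEUTROPHIL, 2.0, 4.0, n_foci=1)
            elif kind == "dots_eosinophil":
                n = max(3, round(24 * scale)) * sev
                _paint_dots(img, fmask, rng, lamina, n, _COL_EOSINOPHIL, 2.0, 3.5, n_foci=1)
            elif kind == "diffuse":
                fmask = _blob_region(rng, lamina, 0.07 * sev, size)
                img[fmask] = 0.55 * img[fmask] + 0.45 * _COL_DIFFUSE
            elif kind == "diffuse_mild":
                fmask = _blob_region(rng, tissue, 0.05 * sev, size)
                img[fmask] = 0.80 * img[fmask] + 0.20 * _COL_MILD
            elif kind == "damage_band":
                near_border = tissue & (dist <= 2.2 * band_depth)
                fmask = _blob_region(rng, near_border, 0.05 * sev, size, sigma=3.0)
                noise = rng.standard_normal(fmask.sum())[:, None] * 5.0
                img[fmask] = 0.30 * img[fmask] + 0.70 * _COL_DAMAGE + noise
            elif kind == "crater":
                r0 = max(10.0, size / 40.0)
                centres = _sample_points_in(rng, epithelium, SEVERITY_MAX, 4.0 * r0)
                for r, c in centres[:sev]:
                    rr, cc = draw.disk((r, c), r0 * 1.6, shape=(size, size))
                    inside = tissue[rr, cc]
                    img[rr[inside], cc[inside]] = (
                        0.2 * img[rr[inside], cc[inside]] + 0.8 * _COL_CRATER
                    )
                    fmask[rr[inside], cc[inside]] = True
            elif kind == "pale_patches":
                n = max(2, round(8 * scale)) * sev
                _paint_dots(img, fmask, rng, lamina, n, _COL_PALE, 7.0, 11.0)
            else:  # pragma: no cover - exhaustive kind map
                raise ScoringError(f"no painter for feature kind {kind!r}")
        feature_masks[name] = fmask

    img[tissue] = np.clip(img[tissue], 20.0, _TISSUE_MAX)

    # per-channel multiplicative stain jitter in optical-density space:
    # OD' = f_c * OD, i.e. I' = 255 * (I / 255) ** f_c; white is invariant
    if spec.stain_jitter > 0:
        factors = sample_stain_factors(_rng(seed, 40), spec.stain_jitter)
        img = apply_stain_jitter(img, factors)

    artefact_mask = np.zeros((size, size), dtype=bool)
    if spec.artefact_fraction > 0 and spec.artefact_types:
        art_rng = _rng(seed, 50)
        margin = max(12.0, size / 32.0)
        interior = tissue & (dist > margin)
        target = spec.artefact_fraction * tissue_area / len(spec.artefact_types)
        for atype in spec.artefact_types:
            radius = float(np.sqrt(target / np.pi))
            centres = _sample_points_in(art_rng, interior, 1, min_dist=0)
            if not centres:
                continue
            r, c = centres[0]
            rr, cc = draw.disk((r, c), radius, shape=(size, size))
            keep = interior[rr, cc]
            rr, cc = rr[keep], cc[keep]
            region = np.zeros((size, size), dtype=bool)
            region[rr, cc] = True
            r0_, r1_ = int(rr.min()), int(rr.max()) + 1
            c0_, c1_ = int(cc.min()), int(cc.max()) + 1
            box = region[r0_:r1_, c0_:c1_]
            if atype == "blank":
                img[region] = 255.0
            elif atype == "blur":
                pad = 24
                pr0, pc0 = max(0, r0_ - pad), max(0, c0_ - pad)
                patch = ndimage.gaussian_filter(
                    img[pr0 : r1_ + pad, pc0 : c1_ + pad], sigma=(8.0, 8.0, 0.0)
                )
                view = img[r0_:r1_, c0_:c1_]
                view[box] = patch[r0_ - pr0 : r0_ - pr0 + box.shape[0],
                                  c0_ - pc0 : c0_ - pc0 + box.shape[1]][box]
            elif atype == "shear_streak":
                theta = art_rng.uniform(0, np.pi)
                yy, xx = np.mgrid[r0_:r1_, c0_:c1_].astype(float)
                phase = yy * np.cos(theta) + xx * np.sin(theta)
                stripes = (phase % 12.0) < 9.0
                view = img[r0_:r1_, c0_:c1_]
                view[box & stripes] = 255.0
            elif atype == "fold":
                img[region] *= 0.25
            artefact_mask |= region

    img8 = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    truth = SyntheticTruth(
        tissue_mask=tissue,
        feature_masks=feature_masks,
        artefact_mask=artefact_mask,
        score=spec.score,
    )
    return img8, truth


@dataclass
class DatasetResult:
    manifest: pd.DataFrame
    images: list[np.ndarray] | None
    truths: list[SyntheticTruth] | None
    out_dir: Path | None


def _quota_counts(probs: np.ndarray, n: int) -> np.ndarray:
    """Largest-remainder allocation of n items to the given proportions."""
    raw = probs * n
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:rem]] += 1
    return counts


def generate_dataset(
    n: int,
    severity_distribution: Mapping[str, Mapping[int, float]],
    *,
    system: System | str = System.GHAS,
    compartment: Compartment | str = Compartment.COLON,
    image_size: int = 1024,
    stain_jitter: float = 0.2,
    artefact_types: Sequence[str] = (),
    artefact_fraction: float = 0.0,
    imbalance: float | None = None,
    biopsies_per_patient: int = 1,
    out_dir: str | os.PathLike | None = None,
    seed: int = 0,
) -> DatasetResult:
    """Generate a labelled synthetic biopsy dataset.

    ``severity_distribution`` maps subgrade name -> {severity: probability};
    each listed subgrade must sum to 1 (tolerance 1e-6) and unlisted
    subgrades stay at severity 0.  Class counts are allocated by quota
    (largest remainder) and shuffled, so empirical frequencies match the
    request to within rounding.  ``imbalance``, if given, overrides the
    first listed subgrade's two-level distribution with a
    majority:minority split of ``imbalance : 1 - imbalance``.

    With ``out_dir`` set, images are written as PNG, truth masks as
    single-channel PNGs under ``masks/``, and the manifest as
    ``manifest.csv`` (columns ``biopsy_id,compartment,path,<subgrades>,
    patient_id``); images/truths are then not retained in memory.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    system = System(system)
    compartment = Compartment(compartment)
    valid = subgrades_for(system)
    severity_distribution = {k: dict(v) for k, v in severity_distribution.items()}
    for name, dist in severity_distribution.items():
        if name not in valid:
            raise ScoringError(f"unknown subgrade {name!r} for {system.value}")
        total = float(sum(dist.values()))
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"distribution for {name!r} sums to {total}, not 1")
    if imbalance is not None:
        first = next(iter(severity_distribution))
        levels = sorted(severity_distribution[first])
        if len(levels) != 2:
            raise ValueError("imbalance override requires a two-level distribution")
        if not 0.0 < imbalance < 1.0:
            raise ValueError("imbalance must lie in (0, 1)")
        severity_distribution[first] = {
            levels[0]: imbalance,
            levels[1]: 1.0 - imbalance,
        }

    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    assigned: dict[str, np.ndarray] = {}
    for name, dist in severity_distribution.items():
        levels = np.array(sorted(dist))
        probs = np.array([dist[int(l)] for l in levels], dtype=float)
        counts = _quota_counts(probs, n)
        col = np.repeat(levels, counts)
        rng.shuffle(col)
        assigned[name] = col
    biopsy_seeds = rng.integers(0, 2**31 - 1, size=n)

    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
        (out_path / "masks").mkdir(exist_ok=True)

    rows = []
    images: list[np.ndarray] | None = [] if out_path is None else None
    truths: list[SyntheticTruth] | None = [] if out_path is None else None
    for i in range(n):
        severities = {name: int(col[i]) for name, col in assigned.items()}
        bid = f"B{i:04d}"
        spec = SyntheticSpec(
            image_size=image_size,
            system=system,
            compartment=compartment,
            subgrade_severities=severities,
            stain_jitter=stain_jitter,
            artefact_types=tuple(artefact_types),
            artefact_fraction=artefact_fraction,
            seed=int(biopsy_seeds[i]),
        )
        img, truth = generate_biopsy(spec)
        if out_path is not None:
            path = out_path / f"{bid}.png"
            iio.imwrite(path, img)
            iio.imwrite(
                out_path / "masks" / f"{bid}_tissue.png",
                (truth.tissue_mask * 255).astype(np.uint8),
            )
            iio.imwrite(
                out_path / "masks" / f"{bid}_artefact.png",
                (truth.artefact_mask * 255).astype(np.uint8),
            )
            for name, fmask in truth.feature_masks.items():
                if fmask.any():
                    iio.imwrite(
                        out_path / "masks" / f"{bid}_feature_{name}.png",
                        (fmask * 255).astype(np.uint8),
                    )
            rel = str(path)
        else:
            images.append(img)  # type: ignore[union-attr]
            truths.append(truth)  # type: ignore[union-attr]
            rel = f"{bid}.png"
        row = {"biopsy_id": bid, "compartment": compartment.value, "path": rel}
        for name in valid:
            row[name] = int(truth.score[name])
        row["patient_id"] = f"P{i // max(1, biopsies_per_patient):04d}"
        rows.append(row)

    manifest = pd.DataFrame(rows)
    if out_path is not None:
        manifest.to_csv(out_path / "manifest.csv", index=False)
    return DatasetResult(manifest=manifest, images=images, truths=truths, out_dir=out_path)
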