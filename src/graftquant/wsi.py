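"""Whole-slide quantification of the CXCL12 chemokine gradient.

A slide is divided into 2048 x 2048-pixel tiles; tiles that are mostly
empty background (> 50% near-white) are discarded. Each retained tile is
unmixed into H/E/DAB optical-density channels; tissue is segmented by
local adaptive (mean) thresholding of the hematoxylin channel, and
CXCL12+ pixels are those whose DAB optical density exceeds 0.035 within
tissue. Slide-level metrics are pixel-sum aggregates: the positive area
fraction (CXCL12+ pixels / tissue pixels) and the staining intensity
normalized to tissue area (summed positive DAB OD / tissue pixels).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from skimage import filters

from .ihc import StainVectors, DEFAULT_STAIN_VECTORS, StainedImage, deconvolve

__all__ = [
    "TileGrid",
    "TileMetrics",
    "SlideMetrics",
    "EmptySlideError",
    "tile",
    "filter_tiles",
    "segment_tissue",
    "positive_regions",
    "aggregate",
    "analyze_slide",
    "compare_groups",
    "DAB_THRESHOLD",
    "EMPTY_LEVEL",
]

DAB_THRESHOLD = 0.035
#: a pixel is "empty" background when min(R, G, B) exceeds this level
EMPTY_LEVEL = 220
TILE_SIZE = 2048


class EmptySlideError(ValueError):
    """No tile with tissue survived filtering; slide metrics undefined."""


@dataclass(frozen=True)
class TileGrid:
    """Non-overlapping tile origins covering an image, with empty fractions."""

    tile_size: int
    image_shape: tuple[int, int]
    origins: tuple[tuple[int, int], ...]
    empty_fraction: tuple[float, ...]


@dataclass(frozen=True)
class TileMetrics:
    """Per-tile tissue/positive pixel bookkeeping."""

    tissue_pixels: int
    positive_pixels: int
    positive_od_sum: float
    mean_positive_od: float
    centroids: tuple[tuple[float, float], ...] = ()


@dataclass(frozen=True)
class SlideMetrics:
    """Slide-level aggregates over retained tiles (pixel sums, not means)."""

    positive_area_fraction: float
    normalized_intensity: float
    mean_positive_od: float
    tissue_pixels: int
    positive_pixels: int
    n_tiles: int
    undefined: bool = False
    centroids: tuple[tuple[float, float], ...] = field(default=(), repr=False)


def tile(image: np.ndarray, size: int = TILE_SIZE) -> TileGrid:
    """Cover an RGB image with size x size tiles, padding edges as empty.

    Padding pixels (beyond the image) count toward a tile's empty fraction.
    """
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("image must be (H, W, 3)")
    h, w = image.shape[:2]
    origins = []
    empties = []
    empty = np.min(image[..., :3], axis=2) > EMPTY_LEVEL
    for r0 in range(0, h, size):
        for c0 in range(0, w, size):
            sub = empty[r0 : r0 + size, c0 : c0 + size]
            n_pad = size * size - sub.size
            frac = (np.count_nonzero(sub) + n_pad) / (size * size)
            origins.append((r0, c0))
            empties.append(float(frac))
    return TileGrid(size, (h, w), tuple(origins), tuple(empties))


def filter_tiles(grid: TileGrid, max_empty: float = 0.5) -> TileGrid:
    """Drop tiles whose empty fraction strictly exceeds ``max_empty``."""
    keep = [i for i, f in enumerate(grid.empty_fraction) if f <= max_empty]
    return TileGrid(
        grid.tile_size,
        grid.image_shape,
        tuple(grid.origins[i] for i in keep),
        tuple(grid.empty_fraction[i] for i in keep),
    )


def get_tile(image: np.ndarray, grid: TileGrid, index: int) -> np.ndarray:
    """Extract one tile, padded with background white where needed."""
    r0, c0 = grid.origins[index]
    s = grid.tile_size
    sub = image[r0 : r0 + s, c0 : c0 + s]
    if sub.shape[:2] == (s, s):
        return sub
    out = np.full((s, s, 3), 255, dtype=image.dtype)
    out[: sub.shape[0], : sub.shape[1]] = sub
    return out


def segment_tissue(
    hematoxylin_od: np.ndarray,
    block_size: int = 255,
    offset: float = -0.02,
    min_od: float = 0.05,
) -> np.ndarray:
    """Tissue mask by local mean thresholding of the hematoxylin channel.

    A pixel is tissue when its OD exceeds the local mean plus ``offset``
    (the negative default makes faintly stained tissue inclusive) and an
    absolute floor ``min_od`` that keeps unstained background out of
    uniformly pale tiles.
    """
    od = np.asarray(hematoxylin_od, dtype=float)
    # threshold_local subtracts its offset from the local mean
    thresh = filters.threshold_local(od, block_size, method="mean", offset=-offset)
    return (od > thresh) & (od > min_od)


def positive_regions(
    dab_od: np.ndarray,
    tissue_mask: np.ndarray,
    dab_threshold: float = DAB_THRESHOLD,
) -> tuple[np.ndarray, TileMetrics]:
    """CXCL12+ mask (DAB OD strictly > threshold, within tissue) + metrics."""
    dab_od = np.asarray(dab_od, dtype=float)
    positive = (dab_od > dab_threshold) & tissue_mask
    n_pos = int(np.count_nonzero(positive))
    od_sum = float(dab_od[positive].sum())
    labels, n_regions = ndimage.label(positive)
    centroids = (
        tuple(map(tuple, ndimage.center_of_mass(positive, labels, range(1, n_regions + 1))))
        if n_regions
        else ()
    )
    return positive, TileMetrics(
        tissue_pixels=int(np.count_nonzero(tissue_mask)),
        positive_pixels=n_pos,
        positive_od_sum=od_sum,
        mean_positive_od=od_sum / n_pos if n_pos else 0.0,
        centroids=centroids,
    )


def aggregate(metrics: list[TileMetrics]) -> SlideMetrics:
    """Pixel-sum aggregation of per-tile metrics into slide metrics."""
    if not metrics:
        raise EmptySlideError("no retained tiles")
    tissue = sum(m.tissue_pixels for m in metrics)
    pos = sum(m.positive_pixels for m in metrics)
    od_sum = sum(m.positive_od_sum for m in metrics)
    cents = tuple(c for m in metrics for c in m.centroids)
    if tissue == 0:
        return SlideMetrics(0.0, 0.0, 0.0, 0, pos, len(metrics), undefined=True)
    return SlideMetrics(
        positive_area_fraction=pos / tissue,
        normalized_intensity=od_sum / tissue,
        mean_positive_od=od_sum / pos if pos else 0.0,
        tissue_pixels=tissue,
        positive_pixels=pos,
        n_tiles=len(metrics),
        centroids=cents,
    )


def analyze_slide(
    image: np.ndarray,
    pixel_size: float = 0.5,
    tile_size: int = TILE_SIZE,
    max_empty: float = 0.5,
    dab_threshold: float = DAB_THRESHOLD,
    stain_vectors: StainVectors = DEFAULT_STAIN_VECTORS,
    block_size: int = 255,
    offset: float = -0.02,
) -> SlideMetrics:
    """Run the full tile-filter-segment-threshold-aggregate pipeline."""
    grid = filter_tiles(tile(image, tile_size), max_empty)
    if not grid.origins:
        raise EmptySlideError("every tile exceeded the empty-area limit")
    per_tile = []
    for i in range(len(grid.origins)):
        rgb = get_tile(image, grid, i)
        od = deconvolve(StainedImage(rgb, pixel_size), stain_vectors)
        tissue = segment_tissue(od.channel("hematoxylin"), block_size, offset)
        _, tm = positive_regions(od.channel("dab"), tissue, dab_threshold)
        per_tile.append(tm)
    return aggregate(per_tile)


def compare_groups(
    values_a: np.ndarray, values_b: np.ndarray
) -> dict[str, float]:
    """Two-sided Mann-Whitney U test between two slide-metric groups.

    Uses the exact null distribution (appropriate for the small biopsy
    groups this assay produces) when there are no ties.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    return {"U": float(res.statistic), "p": float(res.pvalue)}
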