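"""CD8+ T cell density in IHC-stained compartments.

Pipeline: H/E/DAB color deconvolution of an RGB brightfield tile into
optical-density channels, Otsu thresholding plus binary morphology on a
configurable channel to extract a vascular (CD34) or tubular (COL-IV)
region of interest, Laplacian-of-Gaussian blob detection of CD8+ cells on
the DAB channel, and the density readout: detected cells inside the ROI
divided by ROI area in mm^2.

Optical density follows Beer-Lambert: OD = -log10((I + 1) / I0) per RGB
band with I0 = 255; concentrations are obtained by projecting onto the
inverse of the stain-vector matrix and clipping negatives to zero. The
default stain basis is the standard published H/E/DAB set (as shipped by
scikit-image).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import color as skcolor
from skimage import filters, morphology
from skimage.feature import blob_log

__all__ = [
    "StainedImage",
    "StainVectors",
    "ODChannels",
    "ROIMask",
    "BlobSet",
    "DensityResult",
    "DeconvolutionError",
    "DegenerateThresholdError",
    "DensityUndefinedError",
    "DEFAULT_STAIN_VECTORS",
    "rgb_to_od",
    "deconvolve",
    "segment_compartment",
    "apply_mask_edits",
    "detect_blobs",
    "density",
    "sigma_range_for_cell",
    "CELL_DIAMETER_UM",
]

I0 = 255.0
CELL_DIAMETER_UM = 8.0

CHANNELS = ("hematoxylin", "eosin", "dab")


class DeconvolutionError(ValueError):
    """Stain matrix is singular or otherwise unusable."""


class DegenerateThresholdError(ValueError):
    """Channel is constant; Otsu threshold undefined."""


class DensityUndefinedError(ValueError):
    """ROI has zero area; density undefined."""


@dataclass(frozen=True)
class StainedImage:
    """RGB tile with physical pixel size in um/pixel.

    ``rgb`` may be 8-bit integers or floats on the same 0..255 scale; a
    float array preserves sub-quantization optical density, which the
    synthetic forward model exploits for exact round-trips.
    """

    rgb: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise ValueError("rgb must be an (H, W, 3) array")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")


@dataclass(frozen=True)
class StainVectors:
    """Rows are unit optical-density vectors for hematoxylin, eosin, DAB."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("stain matrix must be 3x3")
        norms = np.linalg.norm(m, axis=1)
        if np.any(norms == 0):
            raise DeconvolutionError("zero stain vector")
        object.__setattr__(self, "matrix", m / norms[:, None])

    @property
    def inverse(self) -> np.ndarray:
        if np.linalg.cond(self.matrix) > 1e12:
            raise DeconvolutionError("stain matrix is singular")
        return np.linalg.inv(self.matrix)


# standard published H/E/DAB optical-density basis
DEFAULT_STAIN_VECTORS = StainVectors(skcolor.rgb_from_hed.copy())


@dataclass(frozen=True)
class ODChannels:
    """Per-pixel stain concentrations (optical density units), (H, W, 3)."""

    od: np.ndarray
    pixel_size: float

    def channel(self, name: str) -> np.ndarray:
        return self.od[..., CHANNELS.index(name)]


@dataclass(frozen=True)
class ROIMask:
    """Binary compartment mask with its physical pixel size."""

    mask: np.ndarray
    compartment: str
    pixel_size: float

    @property
    def area_um2(self) -> float:
        return float(np.count_nonzero(self.mask)) * self.pixel_size**2

    @property
    def area_mm2(self) -> float:
        return self.area_um2 / 1e6


@dataclass(frozen=True)
class BlobSet:
    """Detected blobs as (row, col, sigma, response) rows."""

    blobs: np.ndarray  # (n, 4)

    def __len__(self) -> int:
        return self.blobs.shape[0]

    @property
    def positions(self) -> np.ndarray:
        return self.blobs[:, :2]


@dataclass(frozen=True)
class DensityResult:
    compartment: str
    count: int
    area_mm2: float
    density_cells_per_mm2: float
    n_outside: int = 0


def rgb_to_od(rgb: np.ndarray) -> np.ndarray:
    """Per-band optical density, -log10((I + 1) / I0), clipped to >= 0."""
    intensity = np.asarray(rgb, dtype=float)
    od = -np.log10((intensity + 1.0) / I0)
    return np.clip(od, 0.0, None)


def deconvolve(
    image: StainedImage, stain_vectors: StainVectors = DEFAULT_STAIN_VECTORS
) -> ODChannels:
    """Unmix an RGB tile into hematoxylin/eosin/DAB concentration channels.

    Negative concentrations (off-basis noise) are clipped to zero.
    """
    od = rgb_to_od(image.rgb)
    conc = od @ stain_vectors.inverse
    return ODChannels(np.clip(conc, 0.0, None), image.pixel_size)


def segment_compartment(
    channel: np.ndarray,
    compartment: str,
    pixel_size: float,
    otsu_offset: float = 0.0,
    morph_sequence: tuple[tuple[str, int], ...] = (
        ("erode", 2),
        ("dilate", 2),
    ),
) -> ROIMask:
    """Otsu-threshold one OD channel, then apply a binary morphology sequence.

    ``morph_sequence`` is an ordered list of ("erode"|"dilate", disk_radius)
    steps; the default is an opening (erosion then dilation with a
    radius-2 disk), which removes speckle without net growth of the ROI
    and hence without biasing its area.
    """
    channel = np.asarray(channel, dtype=float)
    if np.ptp(channel) == 0:
        raise DegenerateThresholdError("channel is constant; cannot threshold")
    thresh = filters.threshold_otsu(channel) + otsu_offset
    mask = channel > thresh
    for op, radius in morph_sequence:
        selem = morphology.disk(radius)
        if op == "erode":
            mask = morphology.erosion(mask, selem)
        elif op == "dilate":
            mask = morphology.dilation(mask, selem)
        else:
            raise ValueError(f"unknown morphology op {op!r}")
    return ROIMask(mask, compartment, pixel_size)


def apply_mask_edits(
    roi: ROIMask,
    add_regions: np.ndarray | None = None,
    remove_regions: np.ndarray | None = None,
) -> ROIMask:
    """Manual ROI correction: union with add_regions, subtract remove_regions.

    Used e.g. to exclude glomeruli whose capsules stain like tubular
    basement membrane. Region masks must match the ROI shape.
    """
    mask = roi.mask.copy()
    for region, name in ((add_regions, "add"), (remove_regions, "remove")):
        if region is not None and region.shape != mask.shape:
            raise ValueError(f"{name}_regions shape does not match mask")
    if add_regions is not None:
        mask |= add_regions.astype(bool)
    if remove_regions is not None:
        mask &= ~remove_regions.astype(bool)
    return ROIMask(mask, roi.compartment, roi.pixel_size)


def sigma_range_for_cell(
    pixel_size: float, cell_diameter_um: float = CELL_DIAMETER_UM
) -> tuple[float, float]:
    """LoG sigma bounds (pixels) bracketing an 8 um cell by +/-50%.

    A Gaussian spot of radius r responds maximally at sigma = r / sqrt(2).
    """
    sigma_px = (cell_diameter_um / 2.0) / np.sqrt(2.0) / pixel_size
    return 0.5 * sigma_px, 1.5 * sigma_px


def detect_blobs(
    channel: np.ndarray,
    sigma_min: float,
    sigma_max: float,
    threshold: float = 0.05,
    num_sigma: int = 10,
    overlap: float = 0.5,
) -> BlobSet:
    """Scale-normalized LoG blob detection with overlap suppression.

    Wraps scikit-image ``blob_log`` and annotates each detection with the
    scale-normalized response at its center. Deterministic.
    """
    if not (0 < sigma_min <= sigma_max):
        raise ValueError("require 0 < sigma_min <= sigma_max")
    channel = np.asarray(channel, dtype=float)
    raw = blob_log(
        channel,
        min_sigma=sigma_min,
        max_sigma=sigma_max,
        num_sigma=num_sigma,
        threshold=threshold,
        overlap=overlap,
    )
    if raw.size == 0:
        return BlobSet(np.empty((0, 4)))
    responses = np.empty(raw.shape[0])
    for i, (r, c, sigma) in enumerate(raw):
        # scale-normalized negative LoG response at the detected scale
        resp = -(sigma**2) * ndimage.gaussian_laplace(channel, sigma)
        responses[i] = resp[int(round(r)), int(round(c))]
    return BlobSet(np.column_stack([raw, responses]))


def density(blobs: BlobSet, roi: ROIMask) -> DensityResult:
    """Cells-per-mm^2 from blob centers falling inside the ROI.

    A blob whose (rounded) center lands on a mask boundary pixel counts as
    inside.
    """
    area = roi.area_mm2
    if area == 0:
        raise DensityUndefinedError("ROI has zero area")
    if len(blobs) == 0:
        return DensityResult(roi.compartment, 0, area, 0.0)
    rows = np.clip(np.rint(blobs.blobs[:, 0]).astype(int), 0, roi.mask.shape[0] - 1)
    cols = np.clip(np.rint(blobs.blobs[:, 1]).astype(int), 0, roi.mask.shape[1] - 1)
    inside = roi.mask[rows, cols]
    count = int(np.count_nonzero(inside))
    return DensityResult(
        roi.compartment, count, area, count / area, n_outside=len(blobs) - count
    )
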