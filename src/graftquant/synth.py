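"""Ground-truthed synthetic inputs for every pipeline stage.

Each generator is a pure function of its seed and spec, and returns the
rendered data together with the truth needed to score the downstream
stage: compartment masks and cell centers for the IHC tile generator,
tissue/positive masks and the exact positive-area fraction for the
whole-slide generator, per-track stop structure for the track generator,
and planted pass/fail labels for the count-matrix generator.

Image synthesis uses the forward Beer-Lambert model
``I = I0 * 10**(-c @ V) - 1`` with I0 = 255, the exact inverse of the
optical-density transform used by the deconvolution step, so noise-free
float renders admit an analytic round-trip oracle. Quantized 8-bit
renders are available for realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .ihc import DEFAULT_STAIN_VECTORS, I0, StainVectors

__all__ = [
    "forward_compose",
    "IhcSpec",
    "IhcTruth",
    "synth_ihc",
    "GradientSpec",
    "WsiTruth",
    "synth_wsi",
    "TrackRegime",
    "INTRAVASCULAR_REGIME",
    "EXTRAVASCULAR_REGIME",
    "synth_tracks",
    "ViolationSpec",
    "CountsTruth",
    "synth_counts",
]


def forward_compose(
    concentrations: np.ndarray,
    stain_vectors: StainVectors = DEFAULT_STAIN_VECTORS,
    quantize: bool = False,
) -> np.ndarray:
    """Render stain concentrations (H, W, 3) to an RGB image.

    With ``quantize=False`` the float render inverts exactly under the
    deconvolution OD transform; with ``quantize=True`` the image is
    rounded to 8-bit as a scanner would deliver it.
    """
    od_rgb = concentrations @ stain_vectors.matrix
    rgb = I0 * np.power(10.0, -od_rgb) - 1.0
    rgb = np.clip(rgb, 0.0, 255.0)
    if quantize:
        return np.round(rgb).astype(np.uint8)
    return rgb


# ---------------------------------------------------------------- IHC tiles


@dataclass(frozen=True)
class IhcSpec:
    """Layout of a synthetic IHC tile.

    The compartment (an axis-aligned rounded region standing for the
    CD34+ vascular or COL-IV+ tubular structure) carries the eosin-like
    compartment stain; cells are DAB spots of ~8 um diameter placed with
    a minimum separation so detections are unambiguous. A hematoxylin
    background covers all tissue.
    """

    shape: tuple[int, int] = (512, 512)
    pixel_size: float = 0.5  # um/pixel
    compartment: str = "vascular"
    compartment_stain: float = 0.6  # eosin concentration inside the ROI
    hematoxylin_bg: float = 0.25
    cell_amplitude: float = 1.0  # peak DAB concentration per cell
    cell_diameter_um: float = 8.0
    min_separation_um: float = 16.0  # >= 4 cell radii
    n_outside: int = 5  # decoy cells outside the compartment


@dataclass(frozen=True)
class IhcTruth:
    mask: np.ndarray
    centers_inside: np.ndarray  # (n, 2) row, col
    centers_outside: np.ndarray
    density_cells_per_mm2: float
    area_mm2: float


def _sample_centers(
    region: np.ndarray,
    n: int,
    min_sep_px: float,
    rng: np.random.Generator,
    taken: list[np.ndarray],
    max_tries: int = 20000,
) -> np.ndarray:
    """Dart-throwing placement of n points in region with min separation."""
    idx = np.argwhere(region)
    pts: list[np.ndarray] = []
    for _ in range(max_tries):
        if len(pts) == n:
            break
        cand = idx[rng.integers(len(idx))].astype(float)
        ok = all(np.linalg.norm(cand - p) >= min_sep_px for p in pts) and all(
            np.linalg.norm(cand - p) >= min_sep_px for p in taken
        )
        if ok:
            pts.append(cand)
    if len(pts) < n:
        raise RuntimeError("could not place cells with required separation")
    return np.array(pts)


def synth_ihc(
    n_cells: int,
    spec: IhcSpec = IhcSpec(),
    stain_vectors: StainVectors = DEFAULT_STAIN_VECTORS,
    noise_sd: float = 0.02,
    seed: int = 0,
    quantize: bool = True,
) -> tuple[np.ndarray, IhcTruth]:
    """Render a compartment tile with ``n_cells`` DAB-stained cells inside.

    Returns the RGB image and the truth (mask, cell centers, density).
    Additive Gaussian noise of ``noise_sd`` OD is applied per stain
    channel before composition.
    """
    rng = np.random.default_rng(seed)
    h, w = spec.shape
    rows, cols = np.mgrid[0:h, 0:w]

    # compartment: a central rounded rectangle occupying ~45% of the tile
    mh, mw = int(h * 0.67), int(w * 0.67)
    r0 = (h - mh) // 2 + rng.integers(-h // 16, h // 16 + 1)
    c0 = (w - mw) // 2 + rng.integers(-w // 16, w // 16 + 1)
    mask = np.zeros((h, w), dtype=bool)
    mask[r0 : r0 + mh, c0 : c0 + mw] = True

    sep_px = spec.min_separation_um / spec.pixel_size
    margin = int(np.ceil(spec.cell_diameter_um / spec.pixel_size))
    inner = np.zeros_like(mask)
    inner[r0 + margin : r0 + mh - margin, c0 + margin : c0 + mw - margin] = True
    centers_in = (
        _sample_centers(inner, n_cells, sep_px, rng, [])
        if n_cells
        else np.empty((0, 2))
    )
    outer = ~mask
    outer[:margin] = outer[-margin:] = False
    outer[:, :margin] = outer[:, -margin:] = False
    # keep decoys clear of the ROI boundary as well
    pad = int(sep_px)
    dil = np.zeros_like(mask)
    dil[
        max(r0 - pad, 0) : r0 + mh + pad, max(c0 - pad, 0) : c0 + mw + pad
    ] = True
    outer &= ~dil
    centers_out = (
        _sample_centers(outer, spec.n_outside, sep_px, rng, list(centers_in))
        if spec.n_outside
        else np.empty((0, 2))
    )

    conc = np.zeros((h, w, 3), dtype=float)
    conc[..., 0] = spec.hematoxylin_bg
    conc[..., 1] = np.where(mask, spec.compartment_stain, 0.0)
    sigma_px = (spec.cell_diameter_um / 2.0) / np.sqrt(2.0) / spec.pixel_size
    dab = np.zeros((h, w), dtype=float)
    for cr, cc in np.vstack([centers_in, centers_out]):
        d2 = (rows - cr) ** 2 + (cols - cc) ** 2
        dab += spec.cell_amplitude * np.exp(-d2 / (2 * sigma_px**2))
    conc[..., 2] = dab
    if noise_sd > 0:
        conc = conc + rng.normal(0.0, noise_sd, conc.shape)
    conc = np.clip(conc, 0.0, None)

    image = forward_compose(conc, stain_vectors, quantize=quantize)
    area_mm2 = mask.sum() * (spec.pixel_size / 1000.0) ** 2
    return image, IhcTruth(
        mask=mask,
        centers_inside=centers_in,
        centers_outside=centers_out,
        density_cells_per_mm2=n_cells / area_mm2,
        area_mm2=area_mm2,
    )


# ------------------------------------------------------------- WSI slides


@dataclass(frozen=True)
class GradientSpec:
    """DAB optical density as a function of position over the tissue.

    ``kind='preserved'`` is a linear interstitial ramp along the column
    axis from dab_min to dab_max; ``kind='disrupted'`` shuffles square
    patches of the same ramp, preserving its histogram (hence positive
    fraction and intensity) while destroying the spatial gradient;
    ``kind='uniform'`` is flat at dab_max.
    """

    kind: str = "preserved"
    dab_min: float = 0.0
    dab_max: float = 0.2
    hematoxylin: float = 0.4
    tissue_fraction: float = 1.0  # leftmost fraction of columns is tissue
    patch: int = 128


@dataclass(frozen=True)
class WsiTruth:
    tissue_mask: np.ndarray
    positive_mask: np.ndarray
    positive_area_fraction: float
    normalized_intensity: float


def synth_wsi(
    size: tuple[int, int],
    spec: GradientSpec = GradientSpec(),
    dab_threshold: float = 0.035,
    seed: int = 0,
    quantize: bool = False,
) -> tuple[np.ndarray, WsiTruth]:
    """Render a slide with a known DAB gradient and exact truth metrics."""
    h, w = size
    tissue = np.zeros((h, w), dtype=bool)
    tissue[:, : max(1, int(round(w * spec.tissue_fraction)))] = True

    cols = np.arange(w, dtype=float)
    tw = tissue[0].sum()
    ramp = spec.dab_min + (spec.dab_max - spec.dab_min) * np.clip(
        cols / max(tw - 1, 1), 0, 1
    )
    dab = np.tile(ramp, (h, 1))
    if spec.kind == "uniform":
        dab = np.full((h, w), spec.dab_max)
    elif spec.kind == "disrupted":
        rng = np.random.default_rng(seed)
        p = spec.patch
        blocks = [
            (r, c)
            for r in range(0, h - p + 1, p)
            for c in range(0, w - p + 1, p)
            if tissue[r : r + p, c : c + p].all()
        ]
        perm = rng.permutation(len(blocks))
        shuffled = dab.copy()
        for (r, c), k in zip(blocks, perm):
            sr, sc = blocks[k]
            shuffled[r : r + p, c : c + p] = dab[sr : sr + p, sc : sc + p]
        dab = shuffled
    elif spec.kind != "preserved":
        raise ValueError(f"unknown gradient kind {spec.kind!r}")
    dab = np.where(tissue, dab, 0.0)

    conc = np.zeros((h, w, 3), dtype=float)
    conc[..., 0] = np.where(tissue, spec.hematoxylin, 0.0)
    conc[..., 2] = dab
    image = forward_compose(conc, quantize=quantize)

    positive = (dab > dab_threshold) & tissue
    n_tissue = int(tissue.sum())
    truth = WsiTruth(
        tissue_mask=tissue,
        positive_mask=positive,
        positive_area_fraction=positive.sum() / n_tissue,
        normalized_intensity=float(dab[positive].sum()) / n_tissue,
    )
    return image, truth


# ----------------------------------------------------------------- tracks


@dataclass(frozen=True)
class TrackRegime:
    """Stop-and-go persistent-random-walk parameters for one compartment.

    Speeds are in um/min; stop_prob is the per-step probability that a
    moving cell enters a stop of stop_duration frames, during which it
    only jitters below the arrest threshold.
    """

    speed_mean: float
    speed_sd: float
    stop_prob: float
    stop_duration: int
    compartment: str
    persistence: float = 0.7
    jitter_um: float = 0.02


#: fast, rarely arrested motility, as seen inside peritubular capillaries
INTRAVASCULAR_REGIME = TrackRegime(8.0, 2.0, 0.10, 5, "intravascular")
#: slow, frequently arrested motility, as seen in the tubulointerstitium
EXTRAVASCULAR_REGIME = TrackRegime(4.0, 1.5, 0.25, 8, "extravascular")


def synth_tracks(
    n_tracks: int,
    regime: TrackRegime,
    dt: float = 30.0,
    n_frames: int = 60,
    seed: int = 0,
    field_um: float = 300.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate stop-and-go 3-D tracks; returns (detections, truth).

    The truth table records each track's realized stop fraction (fraction
    of inter-frame intervals spent stopped), which the arrest coefficient
    should recover.
    """
    rng = np.random.default_rng(seed)
    rows = []
    truth_rows = []
    for tid in range(n_tracks):
        pos = rng.uniform(0, field_um, 3)
        pos[2] *= 0.1  # shallow imaging volume
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        stopped_left = 0
        n_stopped = 0
        rows.append(
            dict(frame=0, t=0.0, cell_id=tid, x=pos[0], y=pos[1], z=pos[2],
                 compartment=regime.compartment)
        )
        for f in range(1, n_frames):
            if stopped_left > 0:
                stopped_left -= 1
                n_stopped += 1
                pos = pos + rng.normal(0.0, regime.jitter_um, 3)
            else:
                if rng.random() < regime.stop_prob and regime.stop_duration > 0:
                    stopped_left = regime.stop_duration - 1
                    n_stopped += 1
                    pos = pos + rng.normal(0.0, regime.jitter_um, 3)
                else:
                    new_dir = regime.persistence * direction + (
                        1 - regime.persistence
                    ) * _random_unit(rng)
                    direction = new_dir / np.linalg.norm(new_dir)
                    speed = max(rng.normal(regime.speed_mean, regime.speed_sd), 0.0)
                    pos = pos + direction * speed * dt / 60.0
            rows.append(
                dict(frame=f, t=f * dt, cell_id=tid, x=pos[0], y=pos[1],
                     z=pos[2], compartment=regime.compartment)
            )
        truth_rows.append(
            dict(
                cell_id=tid,
                compartment=regime.compartment,
                stop_fraction=n_stopped / (n_frames - 1),
                speed_mean=regime.speed_mean,
            )
        )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


# ---------------------------------------------------------- count matrices


@dataclass(frozen=True)
class ViolationSpec:
    """How many cells/genes violate each QC rule."""

    n_low_gene_cells: int = 0
    n_high_gene_cells: int = 0
    n_high_mito_cells: int = 0
    n_rare_genes: int = 0


@dataclass(frozen=True)
class CountsTruth:
    cell_pass: np.ndarray  # bool per cell
    gene_pass: np.ndarray  # bool per gene
    violation: list[str]  # per cell: "", "low_genes", "high_genes", "high_mito"


def synth_counts(
    n_genes: int = 5000,
    n_cells: int = 300,
    violations: ViolationSpec = ViolationSpec(),
    n_mito_genes: int = 13,
    seed: int = 0,
):
    """Negative-binomial UMI matrix with planted QC violations.

    Baseline gene means are drawn uniformly from [0.1, 2] so every
    ordinary gene is expressed in far more than 10 cells and every
    ordinary cell detects a few thousand genes -- comfortably inside the
    QC window. Planted violations: low-gene cells keep only 100 expressed
    genes; high-gene cells express > 4000 genes; high-mito cells receive
    a mitochondrial UMI spike; rare genes are restricted to 5 cells.
    Returns (CountMatrix, CountsTruth).
    """
    from .sclineage import CountMatrix

    if violations.n_high_gene_cells and n_genes <= 4000:
        raise ValueError("high-gene violations require n_genes > 4000")
    rng = np.random.default_rng(seed)
    means = rng.uniform(0.1, 2.0, n_genes)
    # mitochondrial genes: low enough that ordinary cells sit far below the
    # 0.3% UMI cap, high enough to pass the 10-cell gene filter
    means[:n_mito_genes] = 0.1
    # NB via gamma-Poisson, dispersion 1
    lam = rng.gamma(1.0, means[:, None], size=(n_genes, n_cells))
    counts = rng.poisson(lam).astype(np.int32)

    genes = [f"MT-G{i}" if i < n_mito_genes else f"GENE{i}" for i in range(n_genes)]
    violation = [""] * n_cells
    cell_ids = rng.permutation(n_cells)
    k = 0
    for _ in range(violations.n_low_gene_cells):
        c = cell_ids[k]; k += 1
        keep = rng.choice(n_genes, 100, replace=False)
        col = np.zeros(n_genes, dtype=np.int32)
        col[keep] = np.maximum(counts[keep, c], 1)
        counts[:, c] = col
        violation[c] = "low_genes"
    for _ in range(violations.n_high_gene_cells):
        c = cell_ids[k]; k += 1
        on = rng.choice(n_genes, 4500, replace=False)
        counts[on, c] = np.maximum(counts[on, c], 1)
        violation[c] = "high_genes"
    for _ in range(violations.n_high_mito_cells):
        c = cell_ids[k]; k += 1
        counts[:n_mito_genes, c] += rng.poisson(20, n_mito_genes).astype(np.int32)
        violation[c] = "high_mito"

    gene_pass = np.ones(n_genes, dtype=bool)
    if violations.n_rare_genes:
        rare = rng.choice(
            np.arange(n_mito_genes, n_genes), violations.n_rare_genes, replace=False
        )
        normal_cells = [c for c in range(n_cells) if violation[c] == ""]
        for g in rare:
            keep_cells = rng.choice(normal_cells, 5, replace=False)
            col = np.zeros(n_cells, dtype=np.int32)
            col[keep_cells] = 1
            counts[g] = col
            gene_pass[g] = False

    cell_pass = np.array([v == "" for v in violation])
    matrix = CountMatrix(sparse.csr_matrix(counts), genes,
                         [f"CELL{j}" for j in range(n_cells)])
    return matrix, CountsTruth(cell_pass, gene_pass, violation)
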