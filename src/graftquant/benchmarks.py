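"""End-to-end recovery benchmarks on ground-truthed synthetic data.

Each function regenerates its inputs from a seed, runs the corresponding
pipeline stage, and scores it against the generator's truth. They are the
single source for both the acceptance test suite and the reporting
script, so the two always measure the same quantities the same way.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment

from . import ihc, insilico, sclineage, synth, tracks as tracks_mod, wsi

__all__ = [
    "deconvolution_roundtrip_error",
    "ihc_recovery",
    "wsi_recovery",
    "simulator_summary",
    "track_summary",
    "counts_qc_agreement",
]


def deconvolution_roundtrip_error(seed: int, n_pixels: int = 10_000) -> float:
    """Max |recovered - true| OD over forward-composed random pixels."""
    rng = np.random.default_rng(seed)
    side = int(np.ceil(np.sqrt(n_pixels)))
    conc = rng.uniform(0.0, 1.0, (side, side, 3))
    image = synth.forward_compose(conc)
    od = ihc.deconvolve(ihc.StainedImage(image, 0.5))
    return float(np.abs(od.od - conc).max())


def ihc_recovery(
    seed: int, n_tiles: int = 100, n_cells: int = 30
) -> dict[str, float]:
    """Cell recovery and density error over seeded synthetic IHC tiles.

    Each tile is pushed through the full pipeline (deconvolution, ROI
    segmentation on the compartment-stain channel, LoG blob detection on
    the DAB channel, density). Recovery matches in-ROI detections to true
    in-ROI centers by nearest assignment within one cell diameter.
    """
    spec = synth.IhcSpec()
    match_px = spec.cell_diameter_um / spec.pixel_size
    rng = np.random.default_rng(seed)
    tile_seeds = rng.integers(0, 2**31 - 1, n_tiles)
    smin, smax = ihc.sigma_range_for_cell(spec.pixel_size)
    matched_total = 0
    density_errors = []
    for ts in tile_seeds:
        image, truth = synth.synth_ihc(n_cells, spec=spec, seed=int(ts))
        od = ihc.deconvolve(ihc.StainedImage(image, spec.pixel_size))
        roi = ihc.segment_compartment(
            od.channel("eosin"), spec.compartment, spec.pixel_size
        )
        blobs = ihc.detect_blobs(od.channel("dab"), smin, smax)
        result = ihc.density(blobs, roi)
        density_errors.append(
            abs(result.density_cells_per_mm2 - truth.density_cells_per_mm2)
            / truth.density_cells_per_mm2
        )
        rows = np.rint(blobs.blobs[:, 0]).astype(int)
        cols = np.rint(blobs.blobs[:, 1]).astype(int)
        in_roi = blobs.positions[roi.mask[rows, cols]] if len(blobs) else np.empty((0, 2))
        matched_total += _count_matches(truth.centers_inside, in_roi, match_px)
    return {
        "recovery_rate": matched_total / (n_tiles * n_cells),
        "mean_density_error": float(np.mean(density_errors)),
    }


def _count_matches(truth_pts: np.ndarray, det_pts: np.ndarray, tol: float) -> int:
    """One-to-one nearest matching count within a distance tolerance."""
    if len(truth_pts) == 0 or len(det_pts) == 0:
        return 0
    d = np.linalg.norm(truth_pts[:, None] - det_pts[None, :], axis=2)
    rows, cols = linear_sum_assignment(d)
    return int((d[rows, cols] <= tol).sum())


def wsi_recovery(seed: int, size: tuple[int, int] = (2048, 2048)) -> dict[str, float]:
    """Positive-area-fraction recovery and tile-size invariance on a
    quantized synthetic gradient slide."""
    image, truth = synth.synth_wsi(size, synth.GradientSpec(), seed=seed,
                                   quantize=True)
    coarse = wsi.analyze_slide(image, tile_size=2048)
    fine = wsi.analyze_slide(image, tile_size=512)
    rel_err = (
        abs(coarse.positive_area_fraction - truth.positive_area_fraction)
        / truth.positive_area_fraction
    )
    return {
        "true_fraction": float(truth.positive_area_fraction),
        "estimated_fraction": float(coarse.positive_area_fraction),
        "fraction_rel_error": float(rel_err),
        "tile_size_abs_diff": float(
            abs(coarse.positive_area_fraction - fine.positive_area_fraction)
        ),
        "intensity_rel_error": float(
            abs(coarse.normalized_intensity - truth.normalized_intensity)
            / truth.normalized_intensity
        ),
    }


def simulator_summary(seed: int, n_replications: int = 50) -> dict[str, float]:
    """Symmetric density ratio plus per-variable ANOVA significance rates.

    Each replication re-runs a three-condition experiment for each of the
    three model variables (contact duration, cell number, compartment
    area) with fresh layouts and seed triplets; the rate is the fraction
    of replications with one-way ANOVA p < 0.05.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, float] = {
        "symmetric_density_ratio": insilico.symmetric_density_ratio(
            int(rng.integers(2**31))
        )
    }
    for kind in ("duration", "ncells", "area"):
        ps = [
            insilico.reference_experiment(kind, int(rng.integers(2**31)))["anova_p"]
            for _ in range(n_replications)
        ]
        out[f"{kind}_significant_rate"] = float(np.mean(np.array(ps) < 0.05))
    return out


def track_summary(seed: int, n_tracks: int = 100) -> dict[str, float]:
    """Stop-fraction recovery and fast/slow regime separation."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    det_fast, truth_fast = synth.synth_tracks(
        n_tracks, synth.INTRAVASCULAR_REGIME, seed=int(rng.integers(2**31))
    )
    det_slow, truth_slow = synth.synth_tracks(
        n_tracks, synth.EXTRAVASCULAR_REGIME, seed=int(rng.integers(2**31))
    )
    det_slow = det_slow.assign(cell_id=det_slow["cell_id"] + n_tracks)
    truth_slow = truth_slow.assign(cell_id=truth_slow["cell_id"] + n_tracks)
    detections = pd.concat([det_fast, det_slow], ignore_index=True)
    truth = pd.concat([truth_fast, truth_slow], ignore_index=True)
    summaries = tracks_mod.summarize_tracks(
        tracks_mod.tracks_from_table(detections)
    )
    merged = summaries.merge(truth, left_on="track_id", right_on="cell_id")
    table = tracks_mod.group_compare(summaries).set_index("metric")
    by_comp = summaries.groupby("compartment")
    return {
        "stop_fraction_recovery_error": float(
            abs(
                merged["arrest_coefficient"].mean() - merged["stop_fraction"].mean()
            )
        ),
        "velocity_p": float(table.loc["mean_velocity", "p"]),
        "arrest_p": float(table.loc["arrest_coefficient", "p"]),
        "intravascular_velocity": float(
            by_comp["mean_velocity"].mean()["intravascular"]
        ),
        "extravascular_velocity": float(
            by_comp["mean_velocity"].mean()["extravascular"]
        ),
        "intravascular_arrest": float(
            by_comp["arrest_coefficient"].mean()["intravascular"]
        ),
        "extravascular_arrest": float(
            by_comp["arrest_coefficient"].mean()["extravascular"]
        ),
    }


def counts_qc_agreement(seed: int) -> dict[str, float]:
    """Agreement between QC decisions and the generator's planted truth."""
    matrix, truth = synth.synth_counts(
        violations=synth.ViolationSpec(
            n_low_gene_cells=5, n_high_gene_cells=3, n_high_mito_cells=4,
            n_rare_genes=10,
        ),
        seed=seed,
    )
    res = sclineage.qc_filter(matrix)
    return {
        "cell_agreement": float((res.cell_kept == truth.cell_pass).mean()),
        "gene_agreement": float((res.gene_kept == truth.gene_pass).mean()),
        "cells_retained": int(res.cell_kept.sum()),
    }
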