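"""Intravital cell-track kinetics.

Detections (frame, t, x, y, z, compartment) are linked frame-to-frame into
tracks by greedy mutual-nearest-neighbor matching under a displacement gate
(no gap closing). Per-track kinetics follow the conventions used for
two-photon T cell imaging:

- step speed: 3-D step length / step duration, in um/min;
- mean velocity: total path length / total elapsed time;
- traveled distance: total 3-D path length;
- arrest coefficient: time-weighted fraction of the track spent moving
  slower than 2 um/min, a surrogate for stable immunological synapse
  formation.

Tracks are labeled intravascular or extravascular; a track that switches
compartment is split at the switch. Group comparisons use Welch's
two-sided t test per metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Track",
    "KineticsSummary",
    "UndefinedKineticsError",
    "link",
    "tracks_from_table",
    "kinetics",
    "summarize_tracks",
    "group_compare",
    "ARREST_THRESHOLD",
]

ARREST_THRESHOLD = 2.0  # um/min

DETECTION_COLUMNS = ["frame", "t", "x", "y", "z", "compartment"]


class UndefinedKineticsError(ValueError):
    """Track has fewer than 2 samples; kinetics undefined."""


@dataclass(frozen=True)
class Track:
    """One cell trajectory: times in seconds, coordinates in micrometres."""

    track_id: int
    t: np.ndarray
    xyz: np.ndarray  # (n, 3)
    compartment: str

    def __post_init__(self) -> None:
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("track times must be strictly increasing")
        if self.xyz.shape != (self.t.size, 3):
            raise ValueError("xyz must be (n, 3) matching t")

    def __len__(self) -> int:
        return self.t.size


@dataclass(frozen=True)
class KineticsSummary:
    track_id: int
    compartment: str
    mean_velocity: float  # path length / elapsed time, um/min
    mean_step_speed: float  # time-weighted mean of step speeds, um/min
    distance: float  # total path length, um
    displacement: float  # straight-line start-to-end distance, um
    arrest_coefficient: float


def link(detections: pd.DataFrame, max_displacement: float) -> list[Track]:
    """Link a detection table into tracks.

    If a ``cell_id`` column is present, detections are grouped by it
    directly. Otherwise candidate frame-to-frame pairs within
    ``max_displacement`` are accepted greedily in order of ascending
    distance (ties broken by previous then current detection index), which
    realizes a deterministic smallest-cost mutual-nearest-neighbor
    assignment; unmatched detections start new tracks.
    """
    det = detections.sort_values(["frame"], kind="stable").reset_index(drop=True)
    if "cell_id" in det.columns and det["cell_id"].notna().all():
        out = []
        for tid, (cid, g) in enumerate(det.groupby("cell_id", sort=True)):
            out.extend(_tracks_from_group(tid, g))
        return _renumber(out)

    frames = sorted(det["frame"].unique())
    track_of = np.full(len(det), -1, dtype=int)
    next_id = 0
    prev_idx: np.ndarray | None = None
    for f in frames:
        cur_idx = det.index[det["frame"] == f].to_numpy()
        if prev_idx is not None:
            pxy = det.loc[prev_idx, ["x", "y", "z"]].to_numpy(dtype=float)
            cxy = det.loc[cur_idx, ["x", "y", "z"]].to_numpy(dtype=float)
            d = np.linalg.norm(pxy[:, None, :] - cxy[None, :, :], axis=2)
            pairs = [
                (d[i, j], i, j)
                for i in range(len(prev_idx))
                for j in range(len(cur_idx))
                if d[i, j] <= max_displacement
            ]
            used_p: set[int] = set()
            used_c: set[int] = set()
            for dist, i, j in sorted(pairs):
                if i in used_p or j in used_c:
                    continue
                used_p.add(i)
                used_c.add(j)
                track_of[cur_idx[j]] = track_of[prev_idx[i]]
        for k in cur_idx:
            if track_of[k] == -1:
                track_of[k] = next_id
                next_id += 1
        prev_idx = cur_idx
    det = det.assign(_track=track_of)
    out = []
    for tid, g in det.groupby("_track", sort=True):
        out.extend(_tracks_from_group(int(tid), g))
    return _renumber(out)


def tracks_from_table(detections: pd.DataFrame) -> list[Track]:
    """Build tracks from a pre-labeled detection table (cell_id required)."""
    if "cell_id" not in detections.columns:
        raise ValueError("detection table lacks a cell_id column")
    return link(detections, max_displacement=np.inf)


def _tracks_from_group(tid: int, g: pd.DataFrame) -> list[Track]:
    """One group of samples -> tracks, split wherever the compartment changes."""
    g = g.sort_values("t", kind="stable")
    t = g["t"].to_numpy(dtype=float)
    xyz = g[["x", "y", "z"]].to_numpy(dtype=float)
    comps = g["compartment"].to_numpy() if "compartment" in g.columns else None
    if comps is None:
        return [Track(tid, t, xyz, "unknown")]
    out = []
    start = 0
    for i in range(1, len(g) + 1):
        if i == len(g) or comps[i] != comps[start]:
            out.append(Track(tid, t[start:i], xyz[start:i], str(comps[start])))
            start = i
    return out


def _renumber(tracks: list[Track]) -> list[Track]:
    return [
        Track(i, tr.t, tr.xyz, tr.compartment) for i, tr in enumerate(tracks)
    ]


def kinetics(
    track: Track, arrest_threshold: float = ARREST_THRESHOLD
) -> KineticsSummary:
    """Per-track kinetic summary (velocities in um/min).

    Step speeds are time-weighted by their own durations, so irregular
    sampling does not bias the arrest coefficient.
    """
    if len(track) < 2:
        raise UndefinedKineticsError("kinetics require >= 2 samples")
    dt_min = np.diff(track.t) / 60.0
    steps = np.linalg.norm(np.diff(track.xyz, axis=0), axis=1)
    speeds = steps / dt_min
    total_time = float(dt_min.sum())
    path = float(steps.sum())
    arrest = float(dt_min[speeds < arrest_threshold].sum() / total_time)
    return KineticsSummary(
        track_id=track.track_id,
        compartment=track.compartment,
        mean_velocity=path / total_time,
        mean_step_speed=float(np.sum(speeds * dt_min) / total_time),
        distance=path,
        displacement=float(np.linalg.norm(track.xyz[-1] - track.xyz[0])),
        arrest_coefficient=arrest,
    )


def summarize_tracks(
    tracks: list[Track],
    arrest_threshold: float = ARREST_THRESHOLD,
    min_samples: int = 2,
) -> pd.DataFrame:
    """Kinetics table over all tracks with at least ``min_samples`` samples."""
    rows = []
    for tr in tracks:
        if len(tr) < max(min_samples, 2):
            continue
        k = kinetics(tr, arrest_threshold)
        rows.append(
            {
                "track_id": k.track_id,
                "compartment": k.compartment,
                "mean_velocity": k.mean_velocity,
                "mean_step_speed": k.mean_step_speed,
                "distance": k.distance,
                "displacement": k.displacement,
                "arrest_coefficient": k.arrest_coefficient,
            }
        )
    return pd.DataFrame(rows)


METRICS = ("mean_velocity", "distance", "arrest_coefficient")


def group_compare(
    summaries: pd.DataFrame,
    group_column: str = "compartment",
    metrics: tuple[str, ...] = METRICS,
) -> pd.DataFrame:
    """Welch two-sided t test per kinetic metric between two groups.

    Returns a table of group means +/- SEM and the t/p per metric.
    """
    groups = summaries[group_column].unique()
    if len(groups) != 2:
        raise ValueError("group comparison requires exactly 2 groups")
    a_lab, b_lab = sorted(groups)
    a = summaries[summaries[group_column] == a_lab]
    b = summaries[summaries[group_column] == b_lab]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    rows = []
    for m in metrics:
        t, p = stats.ttest_ind(a[m], b[m], equal_var=False)
        rows.append(
            {
                "metric": m,
                "group_a": a_lab,
                "group_b": b_lab,
                "mean_a": float(a[m].mean()),
                "sem_a": float(stats.sem(a[m])),
                "mean_b": float(b[m].mean()),
                "sem_b": float(stats.sem(b[m])),
                "t": float(t),
                "p": float(p),
            }
        )
    return pd.DataFrame(rows)
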