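"""Agent-based model of T cell-compartment contact dynamics.

Circular cells wander a 2-D canvas with random speed and heading. Two
labeled compartments ("red" and "blue") of predefined areas are placed at
random on the canvas; a cell whose center enters a compartment freezes for
that compartment's contact duration, then resumes in a random direction at
a random speed, displaced one cell radius outward so it cannot refreeze on
the same step. Snapshots record the number of immobilized cells per
compartment, converted to a physical density (cells/mm^2) by scaling one
simulated cell diameter to 8 um -- the average CD8+ T cell size.

The model isolates which of three variables -- infiltrating cell number,
relative compartment area, or contact duration -- can produce an
area-normalized density asymmetry between compartments in a biopsy-like
snapshot.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CompartmentLayout",
    "SimulationConfig",
    "SimulationState",
    "DensityRecord",
    "PlacementError",
    "make_layout",
    "step",
    "run_simulation",
    "records_to_frame",
    "compare_conditions",
]

#: physical diameter assigned to one simulated cell, in micrometres
CELL_DIAMETER_UM = 8.0

LABELS = ("red", "blue")


class PlacementError(ValueError):
    """Requested compartment areas cannot be placed without overlap."""


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangular compartment."""

    label: str
    x0: float
    y0: float
    width: float
    height: float

    @property
    def area(self) -> float:
        return self.width * self.height

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return (
            (x >= self.x0)
            & (x <= self.x0 + self.width)
            & (y >= self.y0)
            & (y <= self.y0 + self.height)
        )


@dataclass(frozen=True)
class CompartmentLayout:
    """Canvas dimensions plus exactly two non-overlapping compartments."""

    canvas_width: float
    canvas_height: float
    compartments: tuple[Rect, Rect]

    def __post_init__(self) -> None:
        if len(self.compartments) != 2:
            raise ValueError("layout requires exactly 2 compartments")
        for c in self.compartments:
            if c.area <= 0:
                raise ValueError(f"compartment {c.label!r} has area <= 0")
            if (
                c.x0 < 0
                or c.y0 < 0
                or c.x0 + c.width > self.canvas_width
                or c.y0 + c.height > self.canvas_height
            ):
                raise ValueError(f"compartment {c.label!r} exceeds canvas")
        a, b = self.compartments
        if _rects_overlap(a, b):
            raise ValueError("compartments overlap")

    @property
    def areas(self) -> dict[str, float]:
        return {c.label: c.area for c in self.compartments}


def _rects_overlap(a: Rect, b: Rect) -> bool:
    return not (
        a.x0 + a.width <= b.x0
        or b.x0 + b.width <= a.x0
        or a.y0 + a.height <= b.y0
        or b.y0 + b.height <= a.y0
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated condition.

    speed_range is in simulation units per tick; contact_duration maps each
    compartment label to a freeze time in ticks; cell_diameter_sim sets the
    physical scale (it corresponds to 8 um).
    """

    n_cells: int
    speed_range: tuple[float, float]
    contact_duration: dict[str, int]
    n_ticks: int
    snapshot_ticks: tuple[int, ...]
    seeds: tuple[int, int, int] = (1, 2, 3)
    cell_diameter_sim: float = 2.0

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        lo, hi = self.speed_range
        if not (0 <= lo <= hi):
            raise ValueError("speed_range must satisfy 0 <= min <= max")
        for lab in LABELS:
            if lab not in self.contact_duration:
                raise ValueError(f"contact_duration missing label {lab!r}")
            if self.contact_duration[lab] < 0:
                raise ValueError("contact durations must be >= 0")
        if len(set(self.seeds)) != len(self.seeds):
            raise ValueError("seeds must be distinct")
        if self.cell_diameter_sim <= 0:
            raise ValueError("cell_diameter_sim must be > 0")


@dataclass
class SimulationState:
    """Per-cell positions, headings, speeds and freeze clocks.

    ``frozen_in`` is -1 for a moving cell, otherwise the index of the
    compartment the cell is frozen in; ``freeze_left`` holds the remaining
    freeze ticks for frozen cells.
    """

    x: np.ndarray
    y: np.ndarray
    heading: np.ndarray
    speed: np.ndarray
    frozen_in: np.ndarray
    freeze_left: np.ndarray
    tick: int = 0

    @property
    def n_cells(self) -> int:
        return self.x.size

    def frozen_counts(self, layout: CompartmentLayout) -> dict[str, int]:
        return {
            c.label: int(np.sum(self.frozen_in == i))
            for i, c in enumerate(layout.compartments)
        }


@dataclass(frozen=True)
class DensityRecord:
    """Immobilized-cell counts and physical densities at one snapshot."""

    tick: int
    seed: int
    counts: dict[str, int]
    areas_mm2: dict[str, float]
    densities: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.densities:
            object.__setattr__(
                self,
                "densities",
                {k: self.counts[k] / self.areas_mm2[k] for k in self.counts},
            )


def physical_area_mm2(sim_area: float, cell_diameter_sim: float) -> float:
    """Convert a simulation-unit area to mm^2 at the 8 um cell-diameter scale."""
    um_per_unit = CELL_DIAMETER_UM / cell_diameter_sim
    return sim_area * (um_per_unit / 1000.0) ** 2


def make_layout(
    canvas_size: tuple[float, float],
    area_red: float,
    area_blue: float,
    seed: int,
    aspect_range: tuple[float, float] = (0.5, 2.0),
    max_tries: int = 1000,
) -> CompartmentLayout:
    """Randomly place two rectangular compartments of the requested areas.

    Rectangle aspect ratios are drawn uniformly from ``aspect_range``;
    placement retries until the rectangles fit inside the canvas without
    overlapping, and raises :class:`PlacementError` after ``max_tries``.
    """
    w, h = canvas_size
    if area_red <= 0 or area_blue <= 0:
        raise ValueError("compartment areas must be > 0")
    if area_red + area_blue > w * h:
        raise PlacementError("compartment areas exceed canvas area")
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        rects = []
        ok = True
        for label, area in zip(LABELS, (area_red, area_blue)):
            aspect = rng.uniform(*aspect_range)
            rw = float(np.sqrt(area * aspect))
            rh = area / rw
            if rw > w or rh > h:
                ok = False
                break
            x0 = rng.uniform(0, w - rw)
            y0 = rng.uniform(0, h - rh)
            rects.append(Rect(label, x0, y0, rw, rh))
        if ok and not _rects_overlap(rects[0], rects[1]):
            return CompartmentLayout(w, h, tuple(rects))
    raise PlacementError(
        f"could not place compartments without overlap in {max_tries} tries"
    )


def init_state(
    config: SimulationConfig, layout: CompartmentLayout, rng: np.random.Generator
) -> SimulationState:
    """Scatter cells uniformly over the canvas with random headings/speeds."""
    n = config.n_cells
    lo, hi = config.speed_range
    return SimulationState(
        x=rng.uniform(0, layout.canvas_width, n),
        y=rng.uniform(0, layout.canvas_height, n),
        heading=rng.uniform(0, 2 * np.pi, n),
        speed=rng.uniform(lo, hi, n),
        frozen_in=np.full(n, -1, dtype=np.int64),
        freeze_left=np.zeros(n, dtype=np.int64),
    )


def _release(
    state: SimulationState,
    idx: np.ndarray,
    layout: CompartmentLayout,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> None:
    """Move released cells one radius beyond the nearest compartment edge."""
    radius = config.cell_diameter_sim / 2.0
    lo, hi = config.speed_range
    for i in idx:
        comp = layout.compartments[state.frozen_in[i]]
        x, y = state.x[i], state.y[i]
        # distance to each rectangle edge; push out through the nearest one
        d = np.array(
            [
                x - comp.x0,  # left
                comp.x0 + comp.width - x,  # right
                y - comp.y0,  # bottom
                comp.y0 + comp.height - y,  # top
            ]
        )
        side = int(np.argmin(d))
        if side == 0:
            x = comp.x0 - radius
        elif side == 1:
            x = comp.x0 + comp.width + radius
        elif side == 2:
            y = comp.y0 - radius
        else:
            y = comp.y0 + comp.height + radius
        state.x[i] = np.clip(x, 0, layout.canvas_width)
        state.y[i] = np.clip(y, 0, layout.canvas_height)
    state.heading[idx] = rng.uniform(0, 2 * np.pi, idx.size)
    state.speed[idx] = rng.uniform(lo, hi, idx.size)
    state.frozen_in[idx] = -1


def step(
    state: SimulationState,
    layout: CompartmentLayout,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> SimulationState:
    """Advance the simulation by one tick, in place.

    Moving cells advance along their heading with reflective canvas
    boundaries; a moving cell whose center enters a compartment freezes for
    that compartment's contact duration (zero-duration compartments never
    hold a cell). Frozen cells decrement their clock and on reaching zero
    are released outward with a fresh random heading and speed.
    """
    frozen = state.frozen_in >= 0
    # frozen cells: decrement, release those reaching 0
    if frozen.any():
        state.freeze_left[frozen] -= 1
        done = frozen & (state.freeze_left <= 0)
        if done.any():
            _release(state, np.flatnonzero(done), layout, config, rng)

    # cells released this tick start moving on the next tick
    moving = ~frozen
    if moving.any():
        dx = state.speed[moving] * np.cos(state.heading[moving])
        dy = state.speed[moving] * np.sin(state.heading[moving])
        x = state.x[moving] + dx
        y = state.y[moving] + dy
        x, hx = _reflect(x, layout.canvas_width)
        y, hy = _reflect(y, layout.canvas_height)
        heading = state.heading[moving].copy()
        heading[hx] = np.pi - heading[hx]
        heading[hy] = -heading[hy]
        state.x[moving] = x
        state.y[moving] = y
        state.heading[moving] = np.mod(heading, 2 * np.pi)

        # freeze on compartment entry (cell-center rule)
        for ci, comp in enumerate(layout.compartments):
            dur = config.contact_duration[comp.label]
            inside = np.zeros(state.n_cells, dtype=bool)
            inside[moving] = comp.contains(state.x[moving], state.y[moving])
            inside &= state.frozen_in < 0
            if dur > 0 and inside.any():
                state.frozen_in[inside] = ci
                state.freeze_left[inside] = dur

    state.tick += 1
    return state


def _reflect(pos: np.ndarray, limit: float) -> tuple[np.ndarray, np.ndarray]:
    hit = (pos < 0) | (pos > limit)
    pos = np.where(pos < 0, -pos, pos)
    pos = np.where(pos > limit, 2 * limit - pos, pos)
    # guard against overshoot beyond one full reflection
    pos = np.clip(pos, 0, limit)
    return pos, hit


def run_simulation(
    config: SimulationConfig, layout: CompartmentLayout
) -> list[DensityRecord]:
    """Run the model once per seed, recording densities at the snapshot ticks.

    Output is deterministic for identical (config, layout, seed).
    """
    if not config.snapshot_ticks:
        raise ValueError("snapshot_ticks must be non-empty")
    if max(config.snapshot_ticks) > config.n_ticks:
        raise ValueError("snapshot ticks exceed n_ticks")
    areas_mm2 = {
        c.label: physical_area_mm2(c.area, config.cell_diameter_sim)
        for c in layout.compartments
    }
    snapshots = set(config.snapshot_ticks)
    records: list[DensityRecord] = []
    for seed in config.seeds:
        rng = np.random.default_rng(seed)
        state = init_state(config, layout, rng)
        for t in range(1, config.n_ticks + 1):
            step(state, layout, config, rng)
            if t in snapshots:
                records.append(
                    DensityRecord(
                        tick=t,
                        seed=seed,
                        counts=state.frozen_counts(layout),
                        areas_mm2=dict(areas_mm2),
                    )
                )
    return records


def records_to_frame(
    records: list[DensityRecord], condition: str = ""
) -> pd.DataFrame:
    """Flatten density records to a tidy table (one row per compartment)."""
    rows = []
    for r in records:
        for lab in LABELS:
            rows.append(
                {
                    "condition": condition,
                    "seed": r.seed,
                    "tick": r.tick,
                    "compartment": lab,
                    "frozen_count": r.counts[lab],
                    "area_mm2": r.areas_mm2[lab],
                    "density_cells_per_mm2": r.densities[lab],
                }
            )
    return pd.DataFrame(rows)


def compare_conditions(
    records_by_condition: dict[str, list[DensityRecord]],
) -> dict:
    """One-way ANOVA on the red-blue density difference across conditions.

    Each (seed, snapshot) pair contributes one replicate of the normalized
    density difference (red - blue, cells/mm^2); condition is the factor.
    Returns per-condition mean differences, the F statistic and p-value.
    A degenerate comparison (zero within-group variance everywhere) is
    flagged rather than assigned a p-value.
    """
    if len(records_by_condition) < 2:
        raise ValueError("need >= 2 conditions for ANOVA")
    groups = {}
    for cond, records in records_by_condition.items():
        diffs = np.array(
            [r.densities["red"] - r.densities["blue"] for r in records], dtype=float
        )
        if diffs.size < 2:
            raise ValueError(f"condition {cond!r} has fewer than 2 replicates")
        groups[cond] = diffs
    means = {c: float(np.mean(d)) for c, d in groups.items()}
    arrays = list(groups.values())
    degenerate = all(np.ptp(d) == 0 for d in arrays) or all(
        d.shape == arrays[0].shape and np.array_equal(d, arrays[0]) for d in arrays
    )
    if degenerate:
        return {
            "mean_diff": means,
            "anova_F": float("nan"),
            "anova_p": float("nan"),
            "degenerate": True,
        }
    f, p = stats.f_oneway(*groups.values())
    return {
        "mean_diff": means,
        "anova_F": float(f),
        "anova_p": float(p),
        "degenerate": False,
    }


# ------------------------------------------------- reference study conditions
#
# The model is exercised under a fixed canvas (400 x 400 units), compartments
# of 8000 units^2 (~5% canvas coverage together), a 2-unit cell diameter
# (1 unit = 4 um, canvas = 1.6 mm), base contact duration 30 ticks, and
# speeds of 60-140 units/tick.  Speeds of the order of the compartment
# spacing make compartment encounters area-proportional (each tick a moving
# cell effectively resamples its neighborhood), which is the regime in which
# area normalization can cancel compartment-size effects and only
# contact-duration asymmetry shifts the normalized density.

CANVAS = (400.0, 400.0)
BASE_AREA = 8000.0
SPEED_RANGE = (60.0, 140.0)
BASE_DURATION = 30
N_CELLS = 500
SNAPSHOTS = (250, 300, 350, 400)
N_TICKS = 400


def _reference_config(
    n_cells: int,
    dur_red: int,
    dur_blue: int,
    seeds: tuple[int, int, int],
    snapshot_ticks: tuple[int, ...] = SNAPSHOTS,
) -> SimulationConfig:
    return SimulationConfig(
        n_cells=n_cells,
        speed_range=SPEED_RANGE,
        contact_duration={"red": dur_red, "blue": dur_blue},
        n_ticks=max(snapshot_ticks),
        snapshot_ticks=snapshot_ticks,
        seeds=seeds,
    )


def reference_experiment(kind: str, master_seed: int) -> dict:
    """Run one three-condition experiment varying a single model input.

    ``kind`` selects which variable differs between conditions:
    ``"duration"`` (red contact duration 1x/2x/4x the blue), ``"ncells"``
    (400/800/1600 infiltrating cells) or ``"area"`` (red:blue compartment
    areas 1:1/2:1/4:1 at constant total). Each condition runs in
    triplicate; returns the :func:`compare_conditions` result.
    """
    rng = np.random.default_rng(master_seed)

    def seeds() -> tuple[int, int, int]:
        return tuple(int(s) for s in rng.integers(0, 2**31 - 1, 3))

    recs: dict[str, list[DensityRecord]] = {}
    if kind == "duration":
        layout = make_layout(CANVAS, BASE_AREA, BASE_AREA, int(rng.integers(2**31)))
        for name, dr in [("1:1", BASE_DURATION), ("2:1", 2 * BASE_DURATION),
                         ("4:1", 4 * BASE_DURATION)]:
            cfg = _reference_config(N_CELLS, dr, BASE_DURATION, seeds())
            recs[name] = run_simulation(cfg, layout)
    elif kind == "ncells":
        layout = make_layout(CANVAS, BASE_AREA, BASE_AREA, int(rng.integers(2**31)))
        for name, n in [("n400", 400), ("n800", 800), ("n1600", 1600)]:
            cfg = _reference_config(n, BASE_DURATION, BASE_DURATION, seeds())
            recs[name] = run_simulation(cfg, layout)
    elif kind == "area":
        total = 2 * BASE_AREA
        for name, frac in [("1:1", 0.5), ("2:1", 2 / 3), ("4:1", 0.8)]:
            layout = make_layout(
                CANVAS, total * frac, total * (1 - frac), int(rng.integers(2**31))
            )
            cfg = _reference_config(N_CELLS, BASE_DURATION, BASE_DURATION, seeds())
            recs[name] = run_simulation(cfg, layout)
    else:
        raise ValueError(f"unknown experiment kind {kind!r}")
    return compare_conditions(recs)


def symmetric_density_ratio(master_seed: int) -> float:
    """Mean red/blue density ratio for a fully symmetric condition.

    Equal areas, equal durations, triplicate seeds; densities are pooled
    over seeds and six late snapshots before taking the ratio.
    """
    rng = np.random.default_rng(master_seed)
    layout = make_layout(CANVAS, BASE_AREA, BASE_AREA, int(rng.integers(2**31)))
    cfg = _reference_config(
        800,
        BASE_DURATION,
        BASE_DURATION,
        tuple(int(s) for s in rng.integers(0, 2**31 - 1, 3)),
        snapshot_ticks=(150, 200, 250, 300, 350, 400),
    )
    recs = run_simulation(cfg, layout)
    red = float(np.mean([r.densities["red"] for r in recs]))
    blue = float(np.mean([r.densities["blue"] for r in recs]))
    return red / blue
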