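"""Seeded stochastic simulator of plate-based nuclei-imaging screens.

The simulator produces ground-truthed wells of immature cardiomyocyte-like
cells: at each 12-hour step a mononucleated cell may enter mitosis with a
density-dependent probability; mitosis resolves either as cytokinesis (two
daughter cells, hyperplastic growth) or as binucleation (one cell gains a
second nucleus, hypertrophic growth). Compounds modulate the division
probability multiplicatively and can impose a per-step death hazard after
an onset time. Wells can be rendered into tiled fluorescence nuclei
images, cell-boundary label images, and per-nucleus marker-intensity
images, always together with the exact ground truth the analysis stages
are tested against.

Division probability falls linearly with well density between two knots
(defaults 136 and 544 cells/mm^2), saturating at ``p_max`` below the low
knot and ``p_confluent`` above the high knot — the minimal shape
consistent with an inverse density–proliferation relationship with a
low-density plateau. Density is the well-level live-cell count divided by
the simulated growth area. Binucleated cells do not re-enter mitosis (a
documented simplification).

Determinism: every stochastic choice flows from one ``numpy``
``SeedSequence``; per-(screen, well) streams are derived with
``spawn_key=(screen, row, col)`` so adding wells or screens never
perturbs the wells already simulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .platemodel import (
    ROLE_CONTROL,
    ROLE_EMPTY,
    PlateMap,
    WellCondition,
    WellTimeSeries,
    well_row_col,
)

__all__ = [
    "DrugEffect",
    "ImagingParams",
    "SimulationConfig",
    "CellTrajectory",
    "SimulatedWell",
    "SimulatedScreen",
    "NEUTRAL_EFFECT",
    "division_probability",
    "simulate_well",
    "simulate_screen",
    "render_nuclei_image",
    "render_marker_image",
    "render_boundary_labels",
    "sample_binucleated_population",
    "expected_fold_change",
    "split_tiles",
]


@dataclass(frozen=True)
class DrugEffect:
    """Per-compound effect: division multiplier and a death hazard.

    death_hazard is a per-12-h probability applied to every live cell at
    steps ending after ``death_onset_h`` hours post-addition. A negative
    onset kills cells in the window between compound addition and the
    first image (time-of-death day 0).
    """

    division_multiplier: float = 1.0
    death_hazard: float = 0.0
    death_onset_h: float = 0.0

    def __post_init__(self) -> None:
        if self.division_multiplier < 0:
            raise ValueError("division multiplier must be >= 0")
        if not 0.0 <= self.death_hazard <= 1.0:
            raise ValueError("death hazard must lie in [0, 1]")


NEUTRAL_EFFECT = DrugEffect()


@dataclass(frozen=True)
class ImagingParams:
    """Geometry and photometry of the rendered well images.

    The simulated arena is the imaged sub-region of a well; its pixel
    extent follows from the tile grid: rows * tile_px - (rows-1) * overlap.
    Nuclei are 2-D Gaussian spots (sigma = nucleus_radius_um / 2) on a
    Poisson background. ``min_spacing_um`` is a hard-core exclusion
    between cell centers (cells have bodies); the two nuclei of a
    binucleated cell sit ``inter_nucleus_um`` apart inside a cell disk of
    ``cell_radius_um``.
    """

    pixel_size_um: float = 2.0
    tile_grid: tuple[int, int] = (2, 2)
    tile_px: int = 320
    tile_overlap_px: int = 16
    nucleus_radius_um: float = 5.0
    spot_amplitude: float = 300.0
    background_level: float = 10.0
    inter_nucleus_um: float = 12.0
    min_spacing_um: float = 16.0
    cell_radius_um: float = 12.0
    render_debris: bool = False
    debris_amplitude: float = 30.0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0 or self.tile_px <= 0:
            raise ValueError("pixel size and tile size must be positive")
        rows, cols = self.tile_grid
        if rows < 1 or cols < 1:
            raise ValueError("tile grid must be at least 1x1")
        if not 0 <= self.tile_overlap_px < self.tile_px:
            raise ValueError("tile overlap must be in [0, tile_px)")

    @property
    def field_shape_px(self) -> tuple[int, int]:
        rows, cols = self.tile_grid
        ov = self.tile_overlap_px
        return (rows * self.tile_px - (rows - 1) * ov,
                cols * self.tile_px - (cols - 1) * ov)

    @property
    def field_um(self) -> tuple[float, float]:
        h, w = self.field_shape_px
        return h * self.pixel_size_um, w * self.pixel_size_um

    @property
    def area_mm2(self) -> float:
        h_um, w_um = self.field_um
        return h_um * w_um / 1e6


@dataclass
class SimulationConfig:
    """All tunables of the well simulator; see module docstring for the model."""

    seed: int = 0
    density: float = 333.0
    p_max: float = 0.05
    p_confluent: float = 0.0
    d_lo: float = 136.0
    d_hi: float = 544.0
    beta: float = 0.15
    initial_binucleated_fraction: float | None = None
    n_timepoints: int = 13
    interval_h: float = 12.0
    drug_effects: dict[str, DrugEffect] = field(default_factory=dict)
    default_effect: DrugEffect | None = NEUTRAL_EFFECT
    imaging: ImagingParams = field(default_factory=ImagingParams)

    def __post_init__(self) -> None:
        for name in ("p_max", "p_confluent", "beta"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.initial_binucleated_fraction is not None and not (
            0.0 <= self.initial_binucleated_fraction <= 1.0
        ):
            raise ValueError("initial binucleated fraction must lie in [0, 1]")
        if not self.d_lo < self.d_hi:
            raise ValueError("density knots must satisfy d_lo < d_hi")
        if self.interval_h <= 0:
            raise ValueError("imaging interval must be positive")
        if self.n_timepoints < 1:
            raise ValueError("need at least one timepoint")

    @property
    def times_h(self) -> np.ndarray:
        return np.arange(self.n_timepoints) * self.interval_h

    def effect_for(self, cond: WellCondition) -> DrugEffect:
        if cond.role in (ROLE_CONTROL, ROLE_EMPTY) or cond.compound_id is None:
            return NEUTRAL_EFFECT
        if cond.compound_id in self.drug_effects:
            return self.drug_effects[cond.compound_id]
        if self.default_effect is not None:
            return self.default_effect
        raise KeyError(
            f"no drug effect configured for compound {cond.compound_id!r} "
            "and no default effect set"
        )


@dataclass
class CellTrajectory:
    """One cell's life: birth, optional binucleation, optional death.

    ``binucleation_h`` is the time the cell gained its second nucleus
    (0.0 for cells plated already binucleated); ``theta`` fixes the axis
    along which the two nuclei separate.
    """

    cell_id: int
    x_um: float
    y_um: float
    birth_h: float = 0.0
    death_h: float | None = None
    binucleation_h: float | None = None
    parent_id: int | None = None
    theta: float = 0.0

    def alive_at(self, t_h: float) -> bool:
        return self.birth_h <= t_h and (self.death_h is None or self.death_h > t_h)

    def nuclei_at(self, t_h: float) -> int:
        return 2 if (self.binucleation_h is not None and self.binucleation_h <= t_h) else 1

    def nucleus_positions_at(self, t_h: float, inter_nucleus_um: float) -> list[tuple[float, float]]:
        if self.nuclei_at(t_h) == 1:
            return [(self.x_um, self.y_um)]
        dx = 0.5 * inter_nucleus_um * math.cos(self.theta)
        dy = 0.5 * inter_nucleus_um * math.sin(self.theta)
        return [(self.x_um - dx, self.y_um - dy), (self.x_um + dx, self.y_um + dy)]


@dataclass
class SimulatedWell:
    well: str
    condition: WellCondition
    trajectories: list[CellTrajectory]
    series: WellTimeSeries


@dataclass
class SimulatedScreen:
    screen: int
    plate_id: str
    wells: dict[str, SimulatedWell]

    def counts_frame(self) -> pd.DataFrame:
        from .platemodel import timeseries_to_frame

        return timeseries_to_frame(
            (sw.series for sw in self.wells.values()), self.plate_id, screen=self.screen
        )


def division_probability(density: float, cfg: SimulationConfig) -> float:
    """Per-12-h division probability at a well density (cells/mm^2).

    p_max for density <= d_lo, p_confluent for density >= d_hi, linear in
    between; continuous and non-increasing when p_max >= p_confluent.
    """
    if density < 0:
        raise ValueError("density must be >= 0")
    return float(np.interp(density, [cfg.d_lo, cfg.d_hi], [cfg.p_max, cfg.p_confluent]))


def _place_cells(
    n: int, rng: np.random.Generator, width_um: float, height_um: float, min_spacing_um: float
) -> np.ndarray:
    """Hard-core placement: uniform positions rejected within min_spacing.

    Falls back to accepting a candidate after 200 rejections so pathological
    densities terminate (spacing then degrades gracefully).
    """
    pts: list[tuple[float, float]] = []
    arr = np.empty((0, 2))
    for _ in range(n):
        for attempt in range(200):
            x = rng.uniform(0, width_um)
            y = rng.uniform(0, height_um)
            if len(pts) == 0:
                break
            d2 = (arr[:, 0] - x) ** 2 + (arr[:, 1] - y) ** 2
            if d2.min() >= min_spacing_um**2:
                break
        pts.append((x, y))
        arr = np.asarray(pts)
    return arr


def _spawn_position(
    parent: CellTrajectory,
    rng: np.random.Generator,
    width_um: float,
    height_um: float,
    min_spacing_um: float,
) -> tuple[float, float]:
    ang = rng.uniform(0, 2 * math.pi)
    dist = min_spacing_um * (1.0 + 0.5 * rng.random())
    x = min(max(parent.x_um + dist * math.cos(ang), 0.0), width_um)
    y = min(max(parent.y_um + dist * math.sin(ang), 0.0), height_um)
    return x, y


def simulate_well(
    cond: WellCondition,
    cfg: SimulationConfig,
    seed: int | np.random.SeedSequence | None = None,
    well: str = "A01",
) -> SimulatedWell:
    """Simulate one well; returns trajectories plus the ground-truth counts.

    Identical (condition, config, seed) yields bit-identical output. The
    per-step order of events is: deaths among cells alive at the step
    start, then divisions among the survivors (daughters appear at the
    step's end and are not at risk within it). Ground-truth counts are
    total nuclei over live cells at each imaging time.
    """
    if seed is None:
        seed = cfg.seed
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    eff = cfg.effect_for(cond)
    height_um, width_um = cfg.imaging.field_um
    area = cfg.imaging.area_mm2

    density = 0.0 if cond.role == ROLE_EMPTY else cond.plating_density
    n0 = int(round(density * area))
    positions = _place_cells(n0, rng, width_um, height_um, cfg.imaging.min_spacing_um)
    b0 = cfg.beta if cfg.initial_binucleated_fraction is None else cfg.initial_binucleated_fraction
    binuc0 = rng.random(n0) < b0
    thetas = rng.uniform(0, 2 * math.pi, size=n0)

    cells = [
        CellTrajectory(
            cell_id=i,
            x_um=float(positions[i, 0]) if n0 else 0.0,
            y_um=float(positions[i, 1]) if n0 else 0.0,
            binucleation_h=0.0 if binuc0[i] else None,
            theta=float(thetas[i]),
        )
        for i in range(n0)
    ]
    next_id = n0

    # death in the addition-to-first-image window (negative onset)
    if eff.death_onset_h < 0 and eff.death_hazard > 0:
        for c in cells:
            if rng.random() < eff.death_hazard:
                c.death_h = 0.0

    times = cfg.times_h
    counts = np.zeros(len(times), dtype=np.int64)
    counts[0] = sum(c.nuclei_at(0.0) for c in cells if c.alive_at(0.0))

    for k in range(1, len(times)):
        t, t_next = times[k - 1], times[k]
        alive = [c for c in cells if c.alive_at(t)]
        dens = len(alive) / area
        p_div = division_probability(dens, cfg) * eff.division_multiplier
        p_div = min(max(p_div, 0.0), 1.0)
        hazard_on = t_next > eff.death_onset_h
        for c in alive:
            if hazard_on and eff.death_hazard > 0 and rng.random() < eff.death_hazard:
                c.death_h = float(t_next)
                continue
            if c.binucleation_h is None and p_div > 0 and rng.random() < p_div:
                if rng.random() < cfg.beta:
                    c.binucleation_h = float(t_next)
                else:
                    x, y = _spawn_position(c, rng, width_um, height_um,
                                           cfg.imaging.min_spacing_um)
                    cells.append(
                        CellTrajectory(
                            cell_id=next_id, x_um=x, y_um=y, birth_h=float(t_next),
                            parent_id=c.cell_id,
                            theta=float(rng.uniform(0, 2 * math.pi)),
                        )
                    )
                    next_id += 1
        counts[k] = sum(c.nuclei_at(t_next) for c in cells if c.alive_at(t_next))

    series = WellTimeSeries(well=well, times_h=times, counts=counts)
    return SimulatedWell(well=well, condition=cond, trajectories=cells, series=series)


def simulate_screen(
    platemap: PlateMap,
    cfg: SimulationConfig,
    n_screens: int = 1,
    seed: int | None = None,
) -> list[SimulatedScreen]:
    """Simulate independent replicate screens of one plate.

    Every treated compound must have an effect in ``cfg.drug_effects`` or a
    ``default_effect``; control wells always receive the neutral effect.
    Per-well seeds derive from ``SeedSequence(seed, spawn_key=(screen, row,
    col))``, so the stream of any given well is independent of which other
    wells exist.
    """
    if seed is None:
        seed = cfg.seed
    if cfg.default_effect is None:
        missing = [c for c in platemap.compounds() if c not in cfg.drug_effects]
        if missing:
            raise KeyError(f"no drug effect configured for compounds {missing}")
    screens: list[SimulatedScreen] = []
    for s in range(n_screens):
        wells: dict[str, SimulatedWell] = {}
        for addr, cond in platemap.wells.items():
            r, c = well_row_col(addr)
            ss = np.random.SeedSequence(seed, spawn_key=(s, r, c))
            wells[addr] = simulate_well(cond, cfg, seed=ss, well=addr)
        screens.append(SimulatedScreen(screen=s, plate_id=platemap.plate_id, wells=wells))
    return screens


def expected_fold_change(
    cond: WellCondition, cfg: SimulationConfig, window: tuple[float, float] = (0.0, 72.0)
) -> float:
    """Mean-field expectation of the raw nuclei fold change of one well.

    Deterministic recursion over the expected mononucleated/binucleated
    cell numbers with density feedback through the expectation; serves as
    an independent closed-form oracle for Monte-Carlo runs and to solve
    for the division multiplier that yields a target normalized effect.
    """
    eff = cfg.effect_for(cond)
    area = cfg.imaging.area_mm2
    b0 = cfg.beta if cfg.initial_binucleated_fraction is None else cfg.initial_binucleated_fraction
    n0 = round(cond.plating_density * area)
    mono, binu = n0 * (1 - b0), n0 * b0
    if eff.death_onset_h < 0:
        mono *= 1 - eff.death_hazard
        binu *= 1 - eff.death_hazard
    nuclei_start = None
    times = cfg.times_h
    t0, t1 = window
    for k, t in enumerate(times):
        if math.isclose(t, t0):
            nuclei_start = mono + 2 * binu
        if math.isclose(t, t1):
            if nuclei_start is None or nuclei_start == 0:
                raise ValueError("window start missing or zero expected count")
            return (mono + 2 * binu) / nuclei_start
        if k == len(times) - 1:
            break
        t_next = times[k + 1]
        dens = (mono + binu) / area
        p = min(max(division_probability(dens, cfg) * eff.division_multiplier, 0.0), 1.0)
        surv = 1 - eff.death_hazard if t_next > eff.death_onset_h else 1.0
        mono_s, binu_s = mono * surv, binu * surv
        divided = p * mono_s
        # cytokinesis: one mono -> two mono; binucleation: mono -> binucleated
        mono = mono_s - divided + 2 * (1 - cfg.beta) * divided
        binu = binu_s + cfg.beta * divided
    raise ValueError(f"window {window} not covered by simulated times")


# ---------------------------------------------------------------------------
# rendering

def _live_nuclei(
    trajectories: Iterable[CellTrajectory], t_h: float, params: ImagingParams
) -> pd.DataFrame:
    rows = []
    for c in trajectories:
        if not c.alive_at(t_h):
            continue
        for j, (x, y) in enumerate(c.nucleus_positions_at(t_h, params.inter_nucleus_um)):
            rows.append({"cell_id": c.cell_id, "nucleus": j, "x_um": x, "y_um": y})
    return pd.DataFrame(rows, columns=["cell_id", "nucleus", "x_um", "y_um"])


def _stamp_spots(
    image: np.ndarray, xs_px: np.ndarray, ys_px: np.ndarray, sigma_px: float, amplitude: float
) -> None:
    """Add Gaussian spots in place; each stamped on a +-4 sigma patch."""
    h, w = image.shape
    r = max(int(math.ceil(4 * sigma_px)), 2)
    for x, y in zip(xs_px, ys_px):
        i0, i1 = int(math.floor(y)) - r, int(math.floor(y)) + r + 1
        j0, j1 = int(math.floor(x)) - r, int(math.floor(x)) + r + 1
        ci0, ci1 = max(i0, 0), min(i1, h)
        cj0, cj1 = max(j0, 0), min(j1, w)
        if ci0 >= ci1 or cj0 >= cj1:
            continue
        ii = np.arange(ci0, ci1)
        jj = np.arange(cj0, cj1)
        gy = np.exp(-0.5 * ((ii - y) / sigma_px) ** 2)
        gx = np.exp(-0.5 * ((jj - x) / sigma_px) ** 2)
        image[ci0:ci1, cj0:cj1] += amplitude * np.outer(gy, gx)


def _render_field(
    truth: pd.DataFrame, params: ImagingParams, rng: np.random.Generator | None,
    debris: pd.DataFrame | None = None,
) -> np.ndarray:
    h, w = params.field_shape_px
    img = np.zeros((h, w), dtype=float)
    sigma_px = (params.nucleus_radius_um / 2.0) / params.pixel_size_um
    if len(truth):
        xs = truth["x_um"].to_numpy() / params.pixel_size_um - 0.5
        ys = truth["y_um"].to_numpy() / params.pixel_size_um - 0.5
        _stamp_spots(img, xs, ys, sigma_px, params.spot_amplitude)
    if debris is not None and len(debris):
        xs = debris["x_um"].to_numpy() / params.pixel_size_um - 0.5
        ys = debris["y_um"].to_numpy() / params.pixel_size_um - 0.5
        _stamp_spots(img, xs, ys, sigma_px, params.debris_amplitude)
    if rng is not None and params.background_level > 0:
        img += rng.poisson(params.background_level, size=img.shape)
    return img


def split_tiles(image: np.ndarray, params: ImagingParams) -> dict[tuple[int, int], np.ndarray]:
    """Cut a rendered field into its overlapping tile grid (row-major keys)."""
    rows, cols = params.tile_grid
    step = params.tile_px - params.tile_overlap_px
    tiles: dict[tuple[int, int], np.ndarray] = {}
    for r in range(rows):
        for c in range(cols):
            i0, j0 = r * step, c * step
            tiles[(r, c)] = image[i0 : i0 + params.tile_px, j0 : j0 + params.tile_px].copy()
    return tiles


def render_nuclei_image(
    trajectories: Sequence[CellTrajectory],
    t_h: float,
    cfg: SimulationConfig,
    seed: int | np.random.SeedSequence | None = None,
) -> tuple[dict[tuple[int, int], np.ndarray], pd.DataFrame]:
    """Render the nuclei channel at time ``t_h`` as overlapping tiles.

    Returns (tiles keyed by (row, col), ground-truth table with one row per
    nucleus: cell_id, nucleus, x_um, y_um, in_field). Nuclei outside the
    field are clipped from the image but kept in the table with
    ``in_field=False``. With ``render_debris`` enabled, nuclei of dead
    cells persist as dim spots (fluorescent debris) that are absent from
    the ground truth.
    """
    params = cfg.imaging
    truth = _live_nuclei(trajectories, t_h, params)
    h_um, w_um = params.field_um
    if len(truth):
        truth["in_field"] = (
            truth["x_um"].between(0, w_um) & truth["y_um"].between(0, h_um)
        )
    else:
        truth["in_field"] = pd.Series(dtype=bool)
    debris = None
    if params.render_debris:
        rows = []
        for c in trajectories:
            if c.death_h is not None and c.death_h <= t_h:
                for x, y in c.nucleus_positions_at(t_h, params.inter_nucleus_um):
                    rows.append({"x_um": x, "y_um": y})
        debris = pd.DataFrame(rows, columns=["x_um", "y_um"])
    rng = None
    if params.background_level > 0:
        ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(
            cfg.seed if seed is None else seed
        )
        rng = np.random.default_rng(ss)
    field = _render_field(truth[truth["in_field"]] if len(truth) else truth,
                          params, rng, debris)
    return split_tiles(field, params), truth


def render_marker_image(
    trajectories: Sequence[CellTrajectory],
    t_h: float,
    cfg: SimulationConfig,
    positive_fraction: float,
    amplitude_ratio: float = 5.0,
    seed: int | np.random.SeedSequence | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a per-nucleus marker channel (Ki67-like) over the same field.

    A seeded fraction of live cells is marker-positive; their nuclei get
    spots ``amplitude_ratio`` times brighter than negatives (which get
    none). Returns the un-tiled marker field plus the ground truth with a
    ``marker_positive`` column.
    """
    params = cfg.imaging
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(
        cfg.seed if seed is None else seed
    )
    rng = np.random.default_rng(ss)
    truth = _live_nuclei(trajectories, t_h, params)
    cell_ids = truth["cell_id"].unique() if len(truth) else np.array([], dtype=int)
    pos_cells = set(cell_ids[rng.random(len(cell_ids)) < positive_fraction])
    truth["marker_positive"] = truth["cell_id"].isin(pos_cells) if len(truth) else False
    pos = truth[truth["marker_positive"]] if len(truth) else truth
    base = replace(params, spot_amplitude=params.spot_amplitude * amplitude_ratio)
    field = _render_field(pos, base, rng)
    return field, truth


def render_boundary_labels(
    trajectories: Sequence[CellTrajectory],
    t_h: float,
    cfg: SimulationConfig,
) -> tuple[np.ndarray, dict[int, int], dict[int, int]]:
    """Render a cell-boundary label image (beta-catenin-like tessellation).

    Each live cell claims the pixels nearest to its center (Voronoi)
    clipped to a disk of ``cell_radius_um``; background is 0. Returns
    (label image, label -> true nuclei count, label -> cell_id). Both
    nuclei of a binucleated cell fall inside its label region because the
    inter-nucleus half-distance is smaller than the cell radius and the
    hard-core half-spacing.
    """
    params = cfg.imaging
    live = [c for c in trajectories if c.alive_at(t_h)]
    h, w = params.field_shape_px
    labels = np.zeros((h, w), dtype=np.int32)
    if not live:
        return labels, {}, {}
    centers = np.array([[c.x_um, c.y_um] for c in live])
    tree = cKDTree(centers)
    yy, xx = np.mgrid[0:h, 0:w]
    pts = np.column_stack(
        [(xx.ravel() + 0.5) * params.pixel_size_um, (yy.ravel() + 0.5) * params.pixel_size_um]
    )
    dist, idx = tree.query(pts)
    lab = np.where(dist <= params.cell_radius_um, idx + 1, 0)
    labels = lab.reshape(h, w).astype(np.int32)
    true_counts = {i + 1: c.nuclei_at(t_h) for i, c in enumerate(live)}
    label_to_cell = {i + 1: c.cell_id for i, c in enumerate(live)}
    return labels, true_counts, label_to_cell


def sample_binucleated_population(
    n_cells: int,
    beta: float,
    cfg: SimulationConfig,
    seed: int | None = None,
) -> list[CellTrajectory]:
    """Fixed-cell snapshot of a population whose binucleation probability is beta.

    Each of ``n_cells`` cells is independently binucleated with
    probability ``beta`` — the population a boundary-stained fixed-cell
    measurement sees. Cells are placed with the configured hard-core
    spacing; the caller renders boundaries and nuclei and recovers beta as
    the measured binucleation proportion (a binomial estimate).
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed if seed is None else seed))
    h_um, w_um = cfg.imaging.field_um
    pos = _place_cells(n_cells, rng, w_um, h_um, cfg.imaging.min_spacing_um)
    binuc = rng.random(n_cells) < beta
    thetas = rng.uniform(0, 2 * math.pi, size=n_cells)
    return [
        CellTrajectory(
            cell_id=i, x_um=float(pos[i, 0]), y_um=float(pos[i, 1]),
            binucleation_h=0.0 if binuc[i] else None, theta=float(thetas[i]),
        )
        for i in range(n_cells)
    ]
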