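"""Plate geometry, plate maps, and per-well time series.

This module holds the canonical data model shared by the simulator, the
image-quantification stage, and the screen analytics: which well contains
which compound at which concentration and plating density, how big a well
is, and the nuclei-count trajectory recorded for each well.

Well addresses are canonicalized to row letter + zero-padded column
("A01"), which sorts lexicographically in plate order.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "PlateMapError",
    "WellCondition",
    "PlateMap",
    "WellGeometry",
    "WellTimeSeries",
    "ROLE_CONTROL",
    "ROLE_TREATED",
    "ROLE_EMPTY",
    "DEFAULT_GROWTH_AREA_MM2",
    "VEHICLE_TAGS",
    "normalize_well_address",
    "well_row_col",
    "density_to_cells_per_well",
    "cells_per_well_to_density",
    "load_platemap",
    "write_platemap",
    "timeseries_to_frame",
    "frame_to_timeseries",
    "write_counts",
    "read_counts",
]


class PlateMapError(ValueError):
    """Raised for malformed plate maps (bad address, duplicate well, no control)."""


ROLE_CONTROL = "control"
ROLE_TREATED = "treated"
ROLE_EMPTY = "empty"
_ROLES = (ROLE_CONTROL, ROLE_TREATED, ROLE_EMPTY)

#: Compound tags accepted on control (vehicle) wells.
VEHICLE_TAGS = frozenset({"DMSO", "dmso", "vehicle", ""})

_ROW_LABELS = {96: "ABCDEFGH", 384: "ABCDEFGHIJKLMNOP"}
_N_COLS = {96: 12, 384: 24}

#: Documented default growth areas (mm^2) per plate format; overridable.
DEFAULT_GROWTH_AREA_MM2 = {96: 32.0, 384: 8.4}

_ADDR_RE = re.compile(r"^([A-Pa-p])0*([0-9]{1,2})$")


def normalize_well_address(address: str, plate_format: int = 384) -> str:
    """Canonicalize a well address ("b7" -> "B07") and validate it.

    Raises :class:`PlateMapError` if the address is malformed or falls
    outside the plate format (96: A1-H12; 384: A1-P24).
    """
    if plate_format not in _ROW_LABELS:
        raise PlateMapError(f"unknown plate format {plate_format!r} (expected 96 or 384)")
    m = _ADDR_RE.match(str(address).strip())
    if not m:
        raise PlateMapError(f"malformed well address {address!r}")
    row, col = m.group(1).upper(), int(m.group(2))
    if row not in _ROW_LABELS[plate_format] or not (1 <= col <= _N_COLS[plate_format]):
        raise PlateMapError(
            f"well address {address!r} outside a {plate_format}-well plate"
        )
    return f"{row}{col:02d}"


def well_row_col(address: str) -> tuple[int, int]:
    """0-based (row, column) indices of a canonical well address."""
    return ord(address[0]) - ord("A"), int(address[1:]) - 1


@dataclass
class WellCondition:
    """Experimental condition of one well.

    compound_id is None (or a vehicle tag) on control wells; concentration
    is in micromolar; plating_density in cells/mm^2.
    """

    role: str
    compound_id: str | None = None
    concentration_um: float = 0.0
    plating_density: float = 333.0

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise PlateMapError(f"invalid role {self.role!r} (expected one of {_ROLES})")
        if self.concentration_um < 0:
            raise PlateMapError("concentration must be >= 0 uM")
        if self.role == ROLE_CONTROL and self.compound_id is not None:
            if self.compound_id not in VEHICLE_TAGS:
                raise PlateMapError(
                    f"control well carries non-vehicle compound {self.compound_id!r}"
                )
        if self.role == ROLE_TREATED and self.concentration_um <= 0:
            raise PlateMapError("treated well requires concentration > 0 uM")
        if self.role == ROLE_EMPTY:
            if self.plating_density < 0:
                raise PlateMapError("plating density must be >= 0")
        elif self.plating_density <= 0:
            raise PlateMapError("plating density must be > 0 cells/mm^2")


@dataclass
class PlateMap:
    """A validated plate map: plate id, format, and well -> condition."""

    plate_id: str
    plate_format: int
    wells: dict[str, WellCondition]

    def __post_init__(self) -> None:
        if self.plate_format not in _ROW_LABELS:
            raise PlateMapError(f"unknown plate format {self.plate_format!r}")
        canonical: dict[str, WellCondition] = {}
        for addr, cond in self.wells.items():
            c = normalize_well_address(addr, self.plate_format)
            if c in canonical:
                raise PlateMapError(f"duplicate well {c!r} in plate {self.plate_id!r}")
            canonical[c] = cond
        self.wells = dict(sorted(canonical.items()))
        if not self.control_wells():
            raise PlateMapError(f"no control well in plate {self.plate_id!r}")

    def control_wells(self) -> list[str]:
        return [w for w, c in self.wells.items() if c.role == ROLE_CONTROL]

    def treated_wells(self) -> list[str]:
        return [w for w, c in self.wells.items() if c.role == ROLE_TREATED]

    def compounds(self) -> list[str]:
        seen = {c.compound_id for c in self.wells.values()
                if c.role == ROLE_TREATED and c.compound_id}
        return sorted(seen)


@dataclass(frozen=True)
class WellGeometry:
    """Physical well geometry used for density <-> cell-count conversion."""

    plate_format: int
    growth_area_mm2: float = 0.0

    def __post_init__(self) -> None:
        if self.plate_format not in _ROW_LABELS:
            raise PlateMapError(f"unknown plate format {self.plate_format!r}")
        if self.growth_area_mm2 == 0.0:
            object.__setattr__(
                self, "growth_area_mm2", DEFAULT_GROWTH_AREA_MM2[self.plate_format]
            )
        if self.growth_area_mm2 <= 0:
            raise PlateMapError("growth area must be positive")


def density_to_cells_per_well(density: float, geom: WellGeometry) -> int:
    """Cells per well for a plating density (cells/mm^2): round(density * area)."""
    if density <= 0:
        raise ValueError(f"plating density must be > 0, got {density}")
    return int(round(density * geom.growth_area_mm2))


def cells_per_well_to_density(cells: int, geom: WellGeometry) -> float:
    """Inverse of :func:`density_to_cells_per_well`, exact to 1/growth_area."""
    if cells < 0:
        raise ValueError("cell count must be non-negative")
    return cells / geom.growth_area_mm2


@dataclass
class WellTimeSeries:
    """Nuclei counts of one well at hours post-compound-addition.

    t = 0 h is the first image after small-molecule addition; subsequent
    points are nominally every 12 h.
    """

    well: str
    times_h: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.times_h.ndim != 1 or self.counts.ndim != 1:
            raise ValueError("times and counts must be 1-D")
        if len(self.times_h) != len(self.counts):
            raise ValueError("times and counts must have equal length")
        if len(self.times_h) and np.any(np.diff(self.times_h) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(self.counts.dtype, np.integer):
            rounded = np.rint(self.counts)
            if not np.allclose(self.counts, rounded):
                raise ValueError("counts must be integers")
            self.counts = rounded.astype(np.int64)

    def count_at(self, t_h: float, atol: float = 1e-6) -> int:
        """Count at an exact imaging time; KeyError if that time was not imaged."""
        idx = np.nonzero(np.isclose(self.times_h, t_h, atol=atol))[0]
        if idx.size == 0:
            raise KeyError(f"no image at t={t_h} h for well {self.well}")
        return int(self.counts[idx[0]])


# ---------------------------------------------------------------------------
# CSV interfaces

_PLATEMAP_COLUMNS = ("well", "compound", "concentration_uM", "role", "density_cells_per_mm2")


def load_platemap(
    path: str | Path,
    plate_id: str | None = None,
    plate_format: int | None = None,
) -> PlateMap:
    """Read a plate-map CSV (columns: well, compound, concentration_uM, role,
    density_cells_per_mm2 — "density" also accepted).

    If plate_format is None it is inferred: 96 when every address fits in
    A1-H12, else 384. Rows with role=empty are retained. Malformed
    addresses, duplicate wells, or a plate without any control well raise
    :class:`PlateMapError` naming the offending row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, comment="#", dtype={"well": str})
    df.columns = [c.strip() for c in df.columns]
    if "density_cells_per_mm2" not in df.columns and "density" in df.columns:
        df = df.rename(columns={"density": "density_cells_per_mm2"})
    missing = [c for c in _PLATEMAP_COLUMNS if c not in df.columns]
    if missing:
        raise PlateMapError(f"plate-map CSV {path} missing columns {missing}")

    if plate_format is None:
        fits_96 = True
        for addr in df["well"]:
            try:
                normalize_well_address(addr, 96)
            except PlateMapError:
                fits_96 = False
                break
        plate_format = 96 if fits_96 else 384

    wells: dict[str, WellCondition] = {}
    dupes: list[str] = []
    for i, row in df.iterrows():
        try:
            addr = normalize_well_address(row["well"], plate_format)
        except PlateMapError as exc:
            raise PlateMapError(f"row {i + 1}: {exc}") from None
        compound = row["compound"]
        compound = None if (pd.isna(compound) or str(compound).strip() == "") else str(compound)
        conc = 0.0 if pd.isna(row["concentration_uM"]) else float(row["concentration_uM"])
        dens = 0.0 if pd.isna(row["density_cells_per_mm2"]) else float(row["density_cells_per_mm2"])
        try:
            cond = WellCondition(
                role=str(row["role"]).strip().lower(),
                compound_id=compound,
                concentration_um=conc,
                plating_density=dens,
            )
        except PlateMapError as exc:
            raise PlateMapError(f"row {i + 1} (well {addr}): {exc}") from None
        if addr in wells:
            dupes.append(addr)
        wells[addr] = cond
    if dupes:
        raise PlateMapError(f"duplicate well(s) {sorted(set(dupes))} in {path}")
    return PlateMap(
        plate_id=plate_id or path.stem, plate_format=plate_format, wells=wells
    )


def write_platemap(platemap: PlateMap, path: str | Path) -> None:
    """Write a plate map back to CSV; round-trips all condition fields."""
    rows = []
    for addr, cond in platemap.wells.items():
        rows.append(
            {
                "well": addr,
                "compound": "" if cond.compound_id is None else cond.compound_id,
                "concentration_uM": cond.concentration_um,
                "role": cond.role,
                "density_cells_per_mm2": cond.plating_density,
            }
        )
    pd.DataFrame(rows, columns=list(_PLATEMAP_COLUMNS)).to_csv(path, index=False)


def timeseries_to_frame(
    series: Iterable[WellTimeSeries], plate_id: str, screen: int | None = None
) -> pd.DataFrame:
    """Long-format counts table (plate_id[, screen], well, time_h, nuclei_count)."""
    rows = []
    for ts in series:
        for t, c in zip(ts.times_h, ts.counts):
            rec = {"plate_id": plate_id, "well": ts.well, "time_h": float(t),
                   "nuclei_count": int(c)}
            if screen is not None:
                rec["screen"] = int(screen)
            rows.append(rec)
    df = pd.DataFrame(rows)
    if screen is not None:
        df = df[["plate_id", "screen", "well", "time_h", "nuclei_count"]]
    return df


def frame_to_timeseries(df: pd.DataFrame) -> dict[str, WellTimeSeries]:
    """Rebuild per-well time series from a long-format counts table."""
    out: dict[str, WellTimeSeries] = {}
    for well, grp in df.groupby("well", sort=True):
        grp = grp.sort_values("time_h")
        out[str(well)] = WellTimeSeries(
            well=str(well),
            times_h=grp["time_h"].to_numpy(),
            counts=grp["nuclei_count"].to_numpy(),
        )
    return out


def write_counts(df: pd.DataFrame, path: str | Path, header: Mapping[str, object] | None = None) -> None:
    """Write a long-format counts CSV, with optional '# key=value' header lines."""
    with open(path, "w") as fh:
        for k, v in (header or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, index=False)


def read_counts(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, comment="#", dtype={"well": str})
    except pd.errors.EmptyDataError:
        return pd.DataFrame()
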