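"""Well-plate containers and readers/writers.

The canonical on-disk form is a matrix CSV mirroring the physical plate
layout: the first row carries the 3OC6-HSL concentrations (nM), the first
column the C8-HSL concentrations (nM), and the body holds specific
luminescence (counts normalized to a path-corrected OD600 of 1.0).  A long
(tidy) CSV dialect with columns ``c8_nM, c6_nM, luminescence`` and read-only
XLSX ingestion (user-configured column mapping) are also supported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("luxfit")

__all__ = ["PlateGrid", "RawPlate", "preprocess_raw", "read_plate", "write_plate"]

#: path-length correction: raw OD600 divided by this equals 1-cm OD600
OD_PATH_FACTOR = 0.46


@dataclass
class PlateGrid:
    """Specific-luminescence matrix on a (C8-HSL x 3OC6-HSL) grid.

    ``L[i, j]`` is the well at ``c8_levels[i]`` nM C8-HSL and
    ``c6_levels[j]`` nM 3OC6-HSL; NaN marks a missing well.  Axes are kept
    strictly ascending (constructors re-sort and permute as needed).
    """

    c8_levels: np.ndarray
    c6_levels: np.ndarray
    L: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.c8_levels = np.asarray(self.c8_levels, dtype=float)
        self.c6_levels = np.asarray(self.c6_levels, dtype=float)
        self.L = np.asarray(self.L, dtype=float)
        if self.L.shape != (self.c8_levels.size, self.c6_levels.size):
            raise ValueError(
                f"luminescence shape {self.L.shape} does not match axes "
                f"({self.c8_levels.size}, {self.c6_levels.size})"
            )
        for name, ax in (("c8", self.c8_levels), ("c6", self.c6_levels)):
            if ax.size == 0:
                raise ValueError(f"{name} axis is empty")
            if np.any(np.diff(ax) == 0):
                raise ValueError(f"duplicate {name} concentration levels")
            if not np.all(np.diff(ax) > 0):  # permute into canonical order
                order = np.argsort(ax)
                if name == "c8":
                    self.c8_levels = ax[order]
                    self.L = self.L[order, :]
                else:
                    self.c6_levels = ax[order]
                    self.L = self.L[:, order]
            if np.any(ax < 0):
                raise ValueError(f"negative {name} concentration")
        present = np.isfinite(self.L)
        if np.any(self.L[present] < 0):
            raise ValueError("negative luminescence value")

    @property
    def mask(self) -> np.ndarray:
        """Boolean matrix, True where the well is present (not missing)."""
        return np.isfinite(self.L)

    @property
    def n_wells(self) -> int:
        return int(self.mask.sum())

    def transposed(self) -> "PlateGrid":
        """Swap the roles of the two concentration axes."""
        return PlateGrid(
            c8_levels=self.c6_levels.copy(),
            c6_levels=self.c8_levels.copy(),
            L=self.L.T.copy(),
            meta=dict(self.meta),
        )


@dataclass
class RawPlate:
    """Raw plate-reader readings before normalization to specific units."""

    od600: np.ndarray
    lum: np.ndarray
    c8_levels: np.ndarray
    c6_levels: np.ndarray
    meta: dict = field(default_factory=dict)


def preprocess_raw(raw: RawPlate) -> PlateGrid:
    """Convert raw OD600/luminescence readings to specific luminescence.

    OD600 is divided by 0.46 to express it at a 1-cm path length, and
    luminescence is normalized to that corrected OD, i.e.
    ``L = lum / (od600 / 0.46)``.  Wells with non-positive OD are flagged
    missing rather than dropped.
    """
    od = np.asarray(raw.od600, dtype=float)
    lum = np.asarray(raw.lum, dtype=float)
    if od.shape != lum.shape:
        raise ValueError("od600 and luminescence matrices differ in shape")
    bad = ~(od > 0)
    if np.any(bad):
        logger.warning("%d wells have non-positive OD600; masked missing", bad.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        L = np.where(bad, np.nan, lum / (od / OD_PATH_FACTOR))
    return PlateGrid(raw.c8_levels, raw.c6_levels, L, meta=dict(raw.meta))


def _detect_format(path: Path) -> str:
    if path.suffix.lower() in (".xlsx", ".xlsm"):
        return "xlsx"
    head = pd.read_csv(path, header=None, nrows=1)
    cols = [str(v).strip().lower() for v in head.iloc[0]]
    if "c8_nm" in cols and "c6_nm" in cols:
        return "long"
    return "matrix"


def read_plate(path, format: str | None = None, xlsx_map: dict | None = None) -> PlateGrid:
    """Read a plate file into canonical form.

    ``format`` is one of ``"matrix"``, ``"long"``, ``"xlsx"`` or None to
    auto-detect.  Non-numeric body cells become missing wells.  For XLSX,
    ``xlsx_map`` must give ``{"sheet": ..., "c8": col, "c6": col, "lum": col}``
    (long layout) since supplementary spreadsheets vary in internal layout.
    """
    path = Path(path)
    fmt = format or _detect_format(path)
    if fmt == "matrix":
        df = pd.read_csv(path, header=None, dtype=str)
        c6 = pd.to_numeric(df.iloc[0, 1:], errors="coerce").to_numpy()
        c8 = pd.to_numeric(df.iloc[1:, 0], errors="coerce").to_numpy()
        if np.any(~np.isfinite(c6)) or np.any(~np.isfinite(c8)):
            raise ValueError(f"non-numeric concentration header in {path}")
        body = df.iloc[1:, 1:].apply(pd.to_numeric, errors="coerce").to_numpy()
        return PlateGrid(c8, c6, body, meta={"source": str(path)})
    if fmt == "long":
        df = pd.read_csv(path)
        df.columns = [str(c).strip().lower() for c in df.columns]
        return _from_long(df, "c8_nm", "c6_nm", "luminescence", str(path))
    if fmt == "xlsx":
        if not xlsx_map:
            raise ValueError("XLSX reading requires an explicit column mapping")
        df = pd.read_excel(path, sheet_name=xlsx_map.get("sheet", 0))
        return _from_long(
            df, xlsx_map["c8"], xlsx_map["c6"], xlsx_map["lum"], str(path)
        )
    raise ValueError(f"unknown plate format {fmt!r}")


def _from_long(df: pd.DataFrame, c8_col, c6_col, lum_col, source: str) -> PlateGrid:
    for col in (c8_col, c6_col, lum_col):
        if col not in df.columns:
            raise ValueError(f"column {col!r} missing from {source}")
    c8 = np.unique(pd.to_numeric(df[c8_col]).to_numpy())
    c6 = np.unique(pd.to_numeric(df[c6_col]).to_numpy())
    L = np.full((c8.size, c6.size), np.nan)
    i = np.searchsorted(c8, pd.to_numeric(df[c8_col]).to_numpy())
    j = np.searchsorted(c6, pd.to_numeric(df[c6_col]).to_numpy())
    vals = pd.to_numeric(df[lum_col], errors="coerce").to_numpy()
    if pd.Series(list(zip(i, j))).duplicated().any():
        raise ValueError(f"duplicate (c8, c6) condition in {source}")
    L[i, j] = vals
    return PlateGrid(c8, c6, L, meta={"source": source})


def write_plate(grid: PlateGrid, path, format: str = "matrix") -> None:
    """Write a plate as matrix CSV (canonical) or long CSV."""
    path = Path(path)
    if format == "matrix":
        df = pd.DataFrame(grid.L, index=grid.c8_levels, columns=grid.c6_levels)
        df.index.name = "c8_nM"
        df.to_csv(path)
    elif format == "long":
        i, j = np.meshgrid(
            np.arange(grid.c8_levels.size), np.arange(grid.c6_levels.size), indexing="ij"
        )
        pd.DataFrame(
            {
                "c8_nM": grid.c8_levels[i.ravel()],
                "c6_nM": grid.c6_levels[j.ravel()],
                "luminescence": grid.L.ravel(),
            }
        ).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown plate format {format!r}")
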