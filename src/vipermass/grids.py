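"""Aligned raster stacks and occurrence points.

Grids are plain 2-D numpy arrays sharing one geometry: cell centers,
row-major storage, origin at the upper-left corner, 0-based indices.
World coordinates follow the usual raster convention — x grows with the
column index, y shrinks with the row index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Altitude band edges in metres; bands are [0, 400), [400, 800), [800, inf).
ALTITUDE_BAND_EDGES = (400.0, 800.0)

#: Human-readable labels for the three altitude bands, in band order.
ALTITUDE_BAND_LABELS = ("0-400", "400-800", ">800")


def altitude_band(elevation):
    """Map elevation in metres to band index 0/1/2.

    Bands are closed on the left and open on the right:
    [0, 400) -> 0, [400, 800) -> 1, [800, inf) -> 2.
    """
    return np.digitize(np.asarray(elevation, dtype=float), ALTITUDE_BAND_EDGES)


def band_label_to_index(label: str) -> int:
    label = str(label).strip()
    try:
        return ALTITUDE_BAND_LABELS.index(label)
    except ValueError:
        raise ValueError(
            f"unknown altitude band {label!r}; expected one of {ALTITUDE_BAND_LABELS}"
        ) from None


@dataclass
class LandscapeStack:
    """Aligned environmental layers over one grid.

    Parameters
    ----------
    covariates
        Array of shape ``(n_covariates, nrows, ncols)`` holding the
        (typically standardized) environmental predictors.
    elevation
        Grid of elevations in metres, shape ``(nrows, ncols)``.
    versant
        Integer-label grid identifying the side of the mountain divide
        (e.g. 0 = Pacific, 1 = Caribbean).
    district
        Integer-label grid partitioning the grid into administrative
        districts.
    cell_size
        Cell width/height in map units.
    origin
        ``(x, y)`` of the grid's upper-left corner.
    nodata_mask
        Boolean grid, ``True`` where cells carry no data. ``None`` means
        every cell is valid.
    """

    covariates: np.ndarray
    elevation: np.ndarray
    versant: np.ndarray
    district: np.ndarray
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    nodata_mask: np.ndarray | None = None

    def __post_init__(self):
        self.covariates = np.asarray(self.covariates, dtype=float)
        if self.covariates.ndim == 2:
            self.covariates = self.covariates[None, :, :]
        self.elevation = np.asarray(self.elevation, dtype=float)
        self.versant = np.asarray(self.versant)
        self.district = np.asarray(self.district)
        shape = self.shape
        for name in ("elevation", "versant", "district"):
            layer = getattr(self, name)
            if layer.shape != shape:
                raise ValueError(
                    f"layer {name!r} has shape {layer.shape}, expected {shape}"
                )
        if self.covariates.shape[1:] != shape:
            raise ValueError("covariate layers misaligned with elevation grid")
        if self.nodata_mask is not None:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != shape:
                raise ValueError("nodata mask misaligned with grid")

    @property
    def shape(self) -> tuple[int, int]:
        return self.elevation.shape

    @property
    def n_covariates(self) -> int:
        return self.covariates.shape[0]

    @property
    def n_cells(self) -> int:
        return self.elevation.size

    def valid_mask(self) -> np.ndarray:
        """Boolean grid of cells that carry data."""
        if self.nodata_mask is None:
            return np.ones(self.shape, dtype=bool)
        return ~self.nodata_mask

    def valid_indices(self) -> np.ndarray:
        """Flat indices (row-major) of valid cells."""
        return np.flatnonzero(self.valid_mask().ravel())

    def cell_center(self, rows, cols) -> tuple[np.ndarray, np.ndarray]:
        """World coordinates of cell centers for given row/col indices."""
        rows = np.asarray(rows)
        cols = np.asarray(cols)
        x = self.origin[0] + (cols + 0.5) * self.cell_size
        y = self.origin[1] - (rows + 0.5) * self.cell_size
        return x, y

    def index_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Row/col indices of the cells containing world points ``(x, y)``.

        Raises ``ValueError`` for points outside the grid extent.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        cols = np.floor((x - self.origin[0]) / self.cell_size).astype(int)
        rows = np.floor((self.origin[1] - y) / self.cell_size).astype(int)
        nrows, ncols = self.shape
        bad = (rows < 0) | (rows >= nrows) | (cols < 0) | (cols >= ncols)
        if np.any(bad):
            raise ValueError(
                f"{int(np.sum(bad))} point(s) fall outside the grid extent"
            )
        return rows, cols


@dataclass
class OccurrenceSet:
    """Species presence points in world coordinates.

    ``points`` has shape ``(n, 2)`` with columns x, y.
    """

    points: np.ndarray

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[1] != 2:
            raise ValueError("points must have two columns (x, y)")

    def __len__(self) -> int:
        return self.points.shape[0]

    def cell_indices(self, stack: LandscapeStack) -> tuple[np.ndarray, np.ndarray]:
        """Resolve points to (rows, cols) on ``stack``."""
        return stack.index_of(self.points[:, 0], self.points[:, 1])

    def unique_cells(self, stack: LandscapeStack) -> np.ndarray:
        """Flat indices of distinct occupied cells (duplicates collapsed)."""
        rows, cols = self.cell_indices(stack)
        flat = rows * stack.shape[1] + cols
        return np.unique(flat)


def check_aligned(*grids: np.ndarray) -> tuple[int, int]:
    """Assert all grids share one shape; return it."""
    shapes = {np.asarray(g).shape for g in grids}
    if len(shapes) != 1:
        raise ValueError(f"grids are misaligned: shapes {sorted(shapes)}")
    return shapes.pop()
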