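"""Aligned raster containers for the modeling grid.

All analysis runs on a single projected (metric) grid: ``Grid2D`` holds one
layer of cell values with a nodata mask, ``LayerStack`` a named collection of
aligned layers. Rows run north to south, columns west to east; ``origin`` is
the outer corner of the top-left cell, so the centre of cell (row, col) is at

    x = origin_x + (col + 0.5) * cell_size
    y = origin_y - (row + 0.5) * cell_size
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Literal

import numpy as np

__all__ = ["Grid2D", "LayerStack", "GeometryError"]

LayerKind = Literal["continuous", "categorical"]


class GeometryError(ValueError):
    """Raised when grids that must share geometry do not."""


@dataclass
class Grid2D:
    """A single raster layer on a metric grid.

    Parameters
    ----------
    values : ndarray of shape (rows, cols)
        Cell values. Masked cells may hold any value (conventionally NaN for
        floats); they are never read.
    cell_size : float
        Cell edge length in metres.
    origin : (float, float)
        (x, y) of the outer corner of the top-left cell.
    nodata_mask : ndarray of bool, optional
        True marks nodata cells. Defaults to all-valid.
    crs_tag : str
        Free-text identifier of the projected reference system.
    """

    values: np.ndarray
    cell_size: float = 1000.0
    origin: tuple[float, float] = (0.0, 0.0)
    nodata_mask: np.ndarray | None = None
    crs_tag: str = "local-metric"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.size < 1:
            raise ValueError("values must be a non-empty 2-D array")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.values.shape:
                raise GeometryError("nodata_mask shape differs from values")
        if np.issubdtype(self.values.dtype, np.floating):
            valid = self.values[~self.nodata_mask]
            if valid.size and not np.all(np.isfinite(valid)):
                raise ValueError("unmasked values must be finite")

    # -- geometry -----------------------------------------------------------
    @property
    def rows(self) -> int:
        return self.values.shape[0]

    @property
    def cols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def same_geometry(self, other: "Grid2D") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size, other.cell_size)
            and np.allclose(self.origin, other.origin)
            and self.crs_tag == other.crs_tag
        )

    def require_same_geometry(self, other: "Grid2D") -> None:
        if not self.same_geometry(other):
            raise GeometryError("grids do not share geometry")

    # -- coordinate transforms ---------------------------------------------
    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the cell containing point (x, y); may be off-grid."""
        col = int(np.floor((x - self.origin[0]) / self.cell_size))
        row = int(np.floor((self.origin[1] - y) / self.cell_size))
        return row, col

    def contains_cell(self, row: int, col: int) -> bool:
        return 0 <= row < self.rows and 0 <= col < self.cols

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x = self.origin[0] + (col + 0.5) * self.cell_size
        y = self.origin[1] - (row + 0.5) * self.cell_size
        return x, y

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (x, y), each of shape (rows, cols), of all cell centres."""
        cols = np.arange(self.cols)
        rows = np.arange(self.rows)
        x = self.origin[0] + (cols + 0.5) * self.cell_size
        y = self.origin[1] - (rows + 0.5) * self.cell_size
        return np.broadcast_to(x, self.shape).copy(), np.broadcast_to(
            y[:, None], self.shape
        ).copy()

    def value_at(self, x: float, y: float) -> float:
        """Value at the cell containing (x, y); NaN if off-grid or masked."""
        row, col = self.cell_of(x, y)
        if not self.contains_cell(row, col) or self.nodata_mask[row, col]:
            return float("nan")
        return float(self.values[row, col])

    # -- convenience --------------------------------------------------------
    def valid_values(self) -> np.ndarray:
        return self.values[~self.nodata_mask]

    def with_values(self, values: np.ndarray, mask: np.ndarray | None = None) -> "Grid2D":
        """A new grid with this geometry and the given values/mask."""
        return Grid2D(
            values=np.asarray(values),
            cell_size=self.cell_size,
            origin=self.origin,
            nodata_mask=self.nodata_mask.copy() if mask is None else np.asarray(mask, bool),
            crs_tag=self.crs_tag,
        )

    def copy(self) -> "Grid2D":
        return replace(self, values=self.values.copy(), nodata_mask=self.nodata_mask.copy())

    # -- text serialization (ESRI ASCII grid) -------------------------------
    NODATA_VALUE = -99999.0

    def to_ascii(self, path: str | Path) -> None:
        """Write as an ESRI ASCII grid (plain text, nodata -99999)."""
        vals = np.where(self.nodata_mask, self.NODATA_VALUE, self.values)
        header = (
            f"ncols {self.cols}\n"
            f"nrows {self.rows}\n"
            f"xllcorner {self.origin[0]!r}\n"
            f"yllcorner {self.origin[1] - self.rows * self.cell_size!r}\n"
            f"cellsize {self.cell_size!r}\n"
            f"NODATA_value {self.NODATA_VALUE!r}\n"
        )
        body = "\n".join(" ".join(repr(float(v)) for v in row) for row in vals)
        Path(path).write_text(header + body + "\n")

    @classmethod
    def from_ascii(cls, path: str | Path, crs_tag: str = "local-metric") -> "Grid2D":
        lines = Path(path).read_text().splitlines()
        hdr = {}
        for line in lines[:6]:
            key, val = line.split()
            hdr[key.lower()] = float(val)
        rows, cols = int(hdr["nrows"]), int(hdr["ncols"])
        cell = hdr["cellsize"]
        nodata = hdr.get("nodata_value", cls.NODATA_VALUE)
        vals = np.array([[float(v) for v in line.split()] for line in lines[6:]])
        mask = vals == nodata
        vals = np.where(mask, np.nan, vals)
        origin = (hdr["xllcorner"], hdr["yllcorner"] + rows * cell)
        return cls(vals, cell_size=cell, origin=origin, nodata_mask=mask, crs_tag=crs_tag)


@dataclass
class LayerStack:
    """Named, aligned raster layers with a continuous/categorical tag each."""

    layers: dict[str, Grid2D] = field(default_factory=dict)
    kinds: dict[str, LayerKind] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ref = None
        for name, grid in self.layers.items():
            if name not in self.kinds:
                raise ValueError(f"layer {name!r} has no kind tag")
            if ref is None:
                ref = grid
            else:
                ref.require_same_geometry(grid)
            if self.kinds[name] == "categorical" and not np.issubdtype(
                grid.values.dtype, np.integer
            ):
                raise ValueError(f"categorical layer {name!r} must hold integer codes")

    def add(self, name: str, grid: Grid2D, kind: LayerKind) -> None:
        if self.layers:
            next(iter(self.layers.values())).require_same_geometry(grid)
        if kind == "categorical" and not np.issubdtype(grid.values.dtype, np.integer):
            raise ValueError(f"categorical layer {name!r} must hold integer codes")
        self.layers[name] = grid
        self.kinds[name] = kind

    def __getitem__(self, name: str) -> Grid2D:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def __iter__(self) -> Iterator[str]:
        return iter(self.layers)

    def __len__(self) -> int:
        return len(self.layers)

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def reference(self) -> Grid2D:
        return next(iter(self.layers.values()))

    def copy(self) -> "LayerStack":
        return LayerStack(
            layers={k: v.copy() for k, v in self.layers.items()},
            kinds=dict(self.kinds),
        )

    def to_dir(self, directory: str | Path) -> None:
        """Write one ASCII grid per layer plus a kinds manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, grid in self.layers.items():
            grid.to_ascii(directory / f"{name}.asc")
        manifest = "".join(f"{n},{k}\n" for n, k in sorted(self.kinds.items()))
        (directory / "layers.csv").write_text("name,kind\n" + manifest)

    @classmethod
    def from_dir(cls, directory: str | Path) -> "LayerStack":
        directory = Path(directory)
        stack = cls()
        rows = (directory / "layers.csv").read_text().splitlines()[1:]
        for row in rows:
            name, kind = row.split(",")
            grid = Grid2D.from_ascii(directory / f"{name}.asc")
            if kind == "categorical":
                vals = np.where(grid.nodata_mask, 0, grid.values).astype(int)
                grid = grid.with_values(vals)
            stack.add(name, grid, kind)  # type: ignore[arg-type]
        return stack
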