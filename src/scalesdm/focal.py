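"""Moving-window (focal) statistics at multiple radii.

The scale-of-effect workflow represents each environmental variable at a set
of candidate spatial scales: the value assigned to a cell is the mean (for
continuous variables) or the class fraction (for categorical variables) over
a circular window of the given radius centred on that cell. Windows are
circular — a neighbour belongs to the window when the Euclidean distance
between cell centres is at most the radius — and are truncated at the grid
border. Nodata cells are excluded from both numerator and denominator, so
window statistics are taken over valid cells only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage

from .grids import Grid2D, LayerStack

__all__ = [
    "MultiScaleLayer",
    "disc_kernel",
    "focal_mean",
    "focal_fraction",
    "build_multiscale_stack",
    "multiscale_layer_name",
]


@dataclass
class MultiScaleLayer:
    """One variable aggregated at one candidate radius."""

    base_name: str
    radius_km: float
    grid: Grid2D
    kind: Literal["continuous", "categorical-fraction"]

    @property
    def name(self) -> str:
        return multiscale_layer_name(self.base_name, self.radius_km)


def multiscale_layer_name(base_name: str, radius_km: float) -> str:
    """Public naming convention for (variable, radius) layers."""
    r = f"{radius_km:g}"
    return f"{base_name}_r{r}km"


def disc_kernel(radius_cells: float) -> np.ndarray:
    """Boolean disc: offsets with centre-to-centre distance <= radius."""
    if radius_cells < 0:
        raise ValueError("radius_cells must be >= 0")
    r = int(np.floor(radius_cells))
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    return (dx * dx + dy * dy) <= radius_cells * radius_cells + 1e-9


def _focal_ratio(numer_field: np.ndarray, valid: np.ndarray, radius_cells: float):
    kernel = disc_kernel(radius_cells).astype(float)
    num = ndimage.correlate(numer_field, kernel, mode="constant", cval=0.0)
    den = ndimage.correlate(valid.astype(float), kernel, mode="constant", cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    return out, den


def focal_mean(grid: Grid2D, radius_cells: float) -> Grid2D:
    """Mean of valid cells within ``radius_cells`` of each cell centre.

    Radius 0 returns the input unchanged (single-cell window). Masked focal
    cells stay masked.
    """
    if radius_cells < 0:
        raise ValueError("radius_cells must be >= 0")
    valid = ~grid.nodata_mask
    vals = np.where(valid, grid.values.astype(float), 0.0)
    out, den = _focal_ratio(vals, valid, radius_cells)
    mask = grid.nodata_mask | (den == 0)
    out = np.where(mask, np.nan, out)
    return grid.with_values(out, mask)


def focal_fraction(grid: Grid2D, class_code: int, radius_cells: float) -> Grid2D:
    """Fraction of valid window cells equal to ``class_code``, in [0, 1]."""
    if radius_cells < 0:
        raise ValueError("radius_cells must be >= 0")
    valid = ~grid.nodata_mask
    hits = np.where(valid & (grid.values == class_code), 1.0, 0.0)
    out, den = _focal_ratio(hits, valid, radius_cells)
    mask = grid.nodata_mask | (den == 0)
    out = np.where(mask, np.nan, np.clip(out, 0.0, 1.0))
    return grid.with_values(out, mask)


def build_multiscale_stack(
    stack: LayerStack,
    radii_km: list[float],
    cell_size: float | None = None,
    categorical_classes: dict[str, dict[str, int]] | None = None,
) -> list[MultiScaleLayer]:
    """One aggregated layer per (variable, radius) pair.

    Continuous layers use :func:`focal_mean`. For each categorical layer,
    ``categorical_classes`` maps the layer name to ``{derived_name: code}``
    and one fraction layer per configured class is produced (so a
    categorical layer contributes ``len(classes)`` layers per radius).
    Radii smaller than half a cell are treated as radius 0 with a warning.
    """
    cell_size = cell_size if cell_size is not None else stack.reference.cell_size
    categorical_classes = categorical_classes or {}
    out: list[MultiScaleLayer] = []
    for radius_km in radii_km:
        radius_cells = radius_km * 1000.0 / cell_size
        if 0 < radius_cells < 0.5:
            warnings.warn(
                f"radius {radius_km} km is below half a cell; treated as 0",
                stacklevel=2,
            )
            radius_cells = 0.0
        for name in stack.names:
            if stack.kinds[name] == "continuous":
                out.append(
                    MultiScaleLayer(
                        base_name=name,
                        radius_km=radius_km,
                        grid=focal_mean(stack[name], radius_cells),
                        kind="continuous",
                    )
                )
            else:
                for derived, code in categorical_classes.get(name, {}).items():
                    out.append(
                        MultiScaleLayer(
                            base_name=derived,
                            radius_km=radius_km,
                            grid=focal_fraction(stack[name], code, radius_cells),
                            kind="categorical-fraction",
                        )
                    )
    return out
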