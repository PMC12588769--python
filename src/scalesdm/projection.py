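"""Scenario projection, binary maps, and habitat-change accounting.

The fitted ensemble is projected onto scenario predictor stacks (focal
layers recomputed at each variable's chosen radius), averaged across
climate-model realizations, and binarized at the current-time maxSSS
threshold. Change between current and future binary maps is summarised as
stable/gain/loss areas with net change and turnover

    turnover = (gain + loss) / (current + gain)

and per-cell trajectories across ordered periods are classified into
never / stable / expansion / contraction / fluctuation time-step maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry.base import BaseGeometry
from shapely import contains_xy

from .ensemble import EnsembleModel
from .focal import multiscale_layer_name
from .grids import GeometryError, Grid2D, LayerStack
from .synthetic import _aggregated_variable

__all__ = [
    "BinaryMap",
    "ChangeSummary",
    "TimeStepMap",
    "TRAJECTORY_CLASSES",
    "extract_features",
    "project_suitability",
    "average_gcms",
    "binarize",
    "apply_dispersal_mask",
    "change_metrics",
    "change_summary_from_areas",
    "time_step_map",
    "resilient_area",
    "bin_suitability",
    "round_half_away",
]

TRAJECTORY_CLASSES = {"NEVER": 0, "STABLE": 1, "EXPANSION": 2, "CONTRACTION": 3, "FLUCTUATION": 4}


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (report-time only; raw values stay exact)."""
    factor = 10.0**ndigits
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


@dataclass
class BinaryMap:
    grid: Grid2D  # values in {0, 1}
    threshold_used: float
    scenario_label: str = "current"
    period_label: str = "current"

    @property
    def suitable_mask(self) -> np.ndarray:
        return (self.grid.values == 1) & ~self.grid.nodata_mask

    def area_km2(self, cell_area_km2: float | None = None) -> float:
        if cell_area_km2 is None:
            cell_area_km2 = (self.grid.cell_size / 1000.0) ** 2
        return float(self.suitable_mask.sum()) * cell_area_km2


@dataclass
class ChangeSummary:
    """Current/future habitat accounting; identities hold exactly:

    area_future = area_stable + area_gain
    area_current = area_stable + area_loss
    """

    area_current: float
    area_stable: float
    area_gain: float
    area_loss: float
    scenario_label: str = ""
    period_label: str = ""

    @property
    def area_future(self) -> float:
        return self.area_stable + self.area_gain

    @property
    def net_change_pct(self) -> float:
        if self.area_current == 0:
            return float("nan")
        return 100.0 * (self.area_future - self.area_current) / self.area_current

    @property
    def turnover_pct(self) -> float:
        denom = self.area_current + self.area_gain
        if denom == 0:
            return float("nan")
        return 100.0 * (self.area_gain + self.area_loss) / denom

    def as_row(self) -> dict:
        return {
            "scenario": self.scenario_label,
            "period": self.period_label,
            "total_area_km2": self.area_future,
            "net_change_pct": round_half_away(self.net_change_pct, 1),
            "area_stable_km2": self.area_stable,
            "area_gain_km2": self.area_gain,
            "area_loss_km2": self.area_loss,
            "turnover_pct": round_half_away(self.turnover_pct, 1),
        }


def extract_features(
    stack: LayerStack, chosen_radii: dict[str, float], cells: list[tuple[int, int]] | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """Feature matrix of chosen-scale variables.

    Recomputes each variable's focal layer at its chosen radius on the given
    stack. With ``cells`` given, one row per cell; otherwise one row per
    grid cell in row-major order. Returns (features, valid_row_mask) where
    invalid rows had a masked value in some layer.
    """
    ref = stack.reference
    cols = {}
    valid = None
    for var in sorted(chosen_radii):
        radius = chosen_radii[var]
        agg = _aggregated_variable(stack, var, radius)
        name = multiscale_layer_name(var, radius)
        if cells is None:
            vals = np.where(agg.nodata_mask, np.nan, agg.values).ravel()
        else:
            vals = np.array(
                [
                    agg.values[r, c]
                    if agg.contains_cell(r, c) and not agg.nodata_mask[r, c]
                    else np.nan
                    for r, c in cells
                ]
            )
        cols[name] = vals
        ok = np.isfinite(vals)
        valid = ok if valid is None else (valid & ok)
    features = pd.DataFrame(cols)
    return features, valid if valid is not None else np.array([], dtype=bool)


def project_suitability(
    ensemble: EnsembleModel, stack: LayerStack, chosen_radii: dict[str, float]
) -> Grid2D:
    """Ensemble suitability on a (current or scenario) predictor stack.

    Focal layers are recomputed at each variable's chosen radius, so
    projecting the training-time stack reproduces the training prediction
    exactly. Cells with any masked predictor are masked.
    """
    ref = stack.reference
    features, valid = extract_features(stack, chosen_radii)
    missing = [v for v in ensemble.variable_set if v not in features.columns]
    if missing:
        raise KeyError(f"scenario stack lacks variables {missing}")
    scores = np.full(len(features), np.nan)
    if valid.any():
        scores[valid] = ensemble.predict(features.loc[valid, ensemble.variable_set])
    grid_vals = scores.reshape(ref.shape)
    mask = ~np.isfinite(grid_vals)
    return ref.with_values(np.nan_to_num(grid_vals), mask)


def average_gcms(suitability_maps: list[Grid2D]) -> Grid2D:
    """Cellwise arithmetic mean across climate-model realizations."""
    if not suitability_maps:
        raise ValueError("need at least one map")
    ref = suitability_maps[0]
    for g in suitability_maps[1:]:
        ref.require_same_geometry(g)
    mask = np.logical_or.reduce([g.nodata_mask for g in suitability_maps])
    mean = np.mean([g.values for g in suitability_maps], axis=0)
    return ref.with_values(np.where(mask, 0.0, mean), mask)


def binarize(
    suitability: Grid2D,
    threshold: float,
    scenario_label: str = "current",
    period_label: str = "current",
) -> BinaryMap:
    """Cell = 1 iff suitability >= threshold (threshold-inclusive)."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    vals = (suitability.values >= threshold).astype(np.int8)
    vals[suitability.nodata_mask] = 0
    grid = suitability.with_values(vals)
    return BinaryMap(grid, threshold, scenario_label, period_label)


def apply_dispersal_mask(
    binary: BinaryMap,
    mode: str = "perfect",
    range_polygon: BaseGeometry | None = None,
    buffer_km: float = 110.0,
) -> BinaryMap:
    """Dispersal constraint on a binary habitat map.

    ``perfect`` returns the map unchanged; ``limited`` zeroes suitable cells
    whose centres fall outside the range polygon buffered by ``buffer_km``.
    """
    if mode == "perfect":
        return BinaryMap(
            binary.grid.copy(), binary.threshold_used, binary.scenario_label, binary.period_label
        )
    if mode != "limited":
        raise ValueError("mode must be 'perfect' or 'limited'")
    if range_polygon is None or range_polygon.is_empty:
        raise ValueError("limited dispersal requires a valid range polygon")
    buffered = range_polygon.buffer(buffer_km * 1000.0)
    x, y = binary.grid.cell_centers()
    inside = contains_xy(buffered, x.ravel(), y.ravel()).reshape(binary.grid.shape)
    vals = np.where(inside, binary.grid.values, 0).astype(np.int8)
    return BinaryMap(
        binary.grid.with_values(vals),
        binary.threshold_used,
        binary.scenario_label,
        binary.period_label,
    )


def change_metrics(
    current: BinaryMap, future: BinaryMap, cell_area_km2: float | None = None
) -> ChangeSummary:
    """Stable/gain/loss accounting between two aligned binary maps."""
    current.grid.require_same_geometry(future.grid)
    if cell_area_km2 is None:
        cell_area_km2 = (current.grid.cell_size / 1000.0) ** 2
    cur = current.suitable_mask
    fut = future.suitable_mask
    stable = float((cur & fut).sum()) * cell_area_km2
    gain = float((~cur & fut).sum()) * cell_area_km2
    loss = float((cur & ~fut).sum()) * cell_area_km2
    return ChangeSummary(
        area_current=float(cur.sum()) * cell_area_km2,
        area_stable=stable,
        area_gain=gain,
        area_loss=loss,
        scenario_label=future.scenario_label,
        period_label=future.period_label,
    )


def change_summary_from_areas(
    area_stable: float,
    area_gain: float,
    area_loss: float,
    scenario_label: str = "",
    period_label: str = "",
) -> ChangeSummary:
    """Accounting from area components directly (current = stable + loss)."""
    return ChangeSummary(
        area_current=area_stable + area_loss,
        area_stable=area_stable,
        area_gain=area_gain,
        area_loss=area_loss,
        scenario_label=scenario_label,
        period_label=period_label,
    )


@dataclass
class TimeStepMap:
    grid: Grid2D  # class codes per TRAJECTORY_CLASSES
    period_labels: list[str] = field(default_factory=list)

    def class_areas(self, cell_area_km2: float | None = None) -> dict[str, float]:
        if cell_area_km2 is None:
            cell_area_km2 = (self.grid.cell_size / 1000.0) ** 2
        valid = ~self.grid.nodata_mask
        return {
            name: float(((self.grid.values == code) & valid).sum()) * cell_area_km2
            for name, code in TRAJECTORY_CLASSES.items()
        }


def _classify_trajectory(traj: tuple[int, ...]) -> int:
    if all(v == 0 for v in traj):
        return TRAJECTORY_CLASSES["NEVER"]
    if all(v == 1 for v in traj):
        return TRAJECTORY_CLASSES["STABLE"]
    diffs = [b - a for a, b in zip(traj, traj[1:])]
    monotone_up = traj[0] == 0 and traj[-1] == 1 and all(d >= 0 for d in diffs)
    monotone_down = traj[0] == 1 and traj[-1] == 0 and all(d <= 0 for d in diffs)
    if monotone_up:
        return TRAJECTORY_CLASSES["EXPANSION"]
    if monotone_down:
        return TRAJECTORY_CLASSES["CONTRACTION"]
    return TRAJECTORY_CLASSES["FLUCTUATION"]


def time_step_map(binaries: list[BinaryMap]) -> TimeStepMap:
    """Per-cell suitability-trajectory classes across ordered periods.

    never (suitable in no period), stable (all periods), expansion (gained
    and never lost again), contraction (lost and never regained),
    fluctuation (any other alternation).
    """
    if len(binaries) < 2:
        raise ValueError("need at least two periods")
    ref = binaries[0].grid
    for b in binaries[1:]:
        ref.require_same_geometry(b.grid)
    stackvals = np.stack([b.suitable_mask.astype(np.int8) for b in binaries])
    codes = np.zeros(ref.shape, dtype=np.int8)
    lut = {}
    flatten = stackvals.reshape(len(binaries), -1)
    for idx in range(flatten.shape[1]):
        traj = tuple(int(v) for v in flatten[:, idx])
        if traj not in lut:
            lut[traj] = _classify_trajectory(traj)
        codes.ravel()[idx] = lut[traj]
    mask = np.logical_or.reduce([b.grid.nodata_mask for b in binaries])
    return TimeStepMap(
        grid=ref.with_values(codes, mask),
        period_labels=[b.period_label for b in binaries],
    )


def resilient_area(binaries: list[BinaryMap], cell_area_km2: float | None = None) -> float:
    """Area suitable in every period (cellwise intersection)."""
    if not binaries:
        raise ValueError("need at least one map")
    if cell_area_km2 is None:
        cell_area_km2 = (binaries[0].grid.cell_size / 1000.0) ** 2
    inter = np.logical_and.reduce([b.suitable_mask for b in binaries])
    return float(inter.sum()) * cell_area_km2


def bin_suitability(suitability: Grid2D, n_bins: int = 5) -> pd.DataFrame:
    """Equal-interval suitability bins as percent of unmasked cells.

    Bins are left-closed ([0.0, 0.2), ...) with the last bin closed on both
    sides.
    """
    vals = suitability.valid_values()
    if vals.size == 0:
        raise ValueError("no unmasked cells")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(vals, edges, right=False) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        rows.append(
            {
                "bin_low": edges[b],
                "bin_high": edges[b + 1],
                "percent": 100.0 * float((idx == b).sum()) / vals.size,
            }
        )
    return pd.DataFrame(rows)
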