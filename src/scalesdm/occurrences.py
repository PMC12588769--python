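"""Occurrence records, cleaning rules, and pseudo-absence sampling.

Presence-only records are cleaned with three exclusion rules (outside the
species' range polygon, outside the plausible elevation band widened by a
buffer, on a land-cover class the species does not use) and then thinned to
one record per grid cell so spatial clustering does not inflate model
performance. Background ("pseudo-absence") points are drawn uniformly from
the valid study grid, excluding presence cells.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from shapely.geometry import Point
from shapely.geometry.base import BaseGeometry

from .grids import Grid2D

__all__ = [
    "OccurrenceRecord",
    "OccurrenceSet",
    "FilterReport",
    "PseudoAbsenceSet",
    "thin_occurrences",
    "filter_occurrences",
    "sample_pseudo_absences",
]


@dataclass(frozen=True)
class OccurrenceRecord:
    x: float
    y: float
    elevation: float | None = None
    year: int | None = None
    source_tag: str | None = None


@dataclass
class OccurrenceSet:
    """An ordered collection of presence records."""

    records: list[OccurrenceRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def coordinates(self) -> np.ndarray:
        return np.array([(r.x, r.y) for r in self.records]).reshape(-1, 2)

    def cells(self, grid: Grid2D) -> list[tuple[int, int]]:
        return [grid.cell_of(r.x, r.y) for r in self.records]

    # -- text I/O -----------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["x", "y", "elevation", "year"])
            for r in self.records:
                writer.writerow(
                    [
                        repr(r.x),
                        repr(r.y),
                        "" if r.elevation is None else repr(float(r.elevation)),
                        "" if r.year is None else r.year,
                    ]
                )

    @classmethod
    def from_csv(cls, path: str | Path) -> "OccurrenceSet":
        records = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                records.append(
                    OccurrenceRecord(
                        x=float(row["x"]),
                        y=float(row["y"]),
                        elevation=float(row["elevation"]) if row.get("elevation") else None,
                        year=int(row["year"]) if row.get("year") else None,
                    )
                )
        return cls(records)

    def to_geojson(self, path: str | Path) -> None:
        features = []
        for r in self.records:
            props: dict = {}
            if r.elevation is not None:
                props["elevation"] = r.elevation
            if r.year is not None:
                props["year"] = r.year
            features.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "Point", "coordinates": [r.x, r.y]},
                    "properties": props,
                }
            )
        Path(path).write_text(
            json.dumps({"type": "FeatureCollection", "features": features}, indent=1)
        )


REJECT_REASONS = (
    "outside_polygon",
    "elevation_out_of_range",
    "landcover_mismatch",
    "duplicate_cell",
)


@dataclass
class FilterReport:
    """Kept records plus per-record rejection reasons.

    Every input record appears exactly once across ``kept`` and ``rejected``.
    """

    kept: OccurrenceSet
    rejected: list[tuple[OccurrenceRecord, str]] = field(default_factory=list)

    @property
    def n_input(self) -> int:
        return len(self.kept) + len(self.rejected)

    def rejected_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["x", "y", "reason"])
            for rec, reason in self.rejected:
                writer.writerow([repr(rec.x), repr(rec.y), reason])


def thin_occurrences(occ: OccurrenceSet, grid: Grid2D) -> FilterReport:
    """Keep at most one record per grid cell.

    Within a cell, records are ranked by year descending (records without a
    year sort last), ties broken by input order; the top-ranked record is
    kept. Off-grid records are never thinned here (they are a polygon-rule
    concern), so they all pass through as kept.
    """
    order = sorted(
        range(len(occ.records)),
        key=lambda i: (
            -(occ.records[i].year if occ.records[i].year is not None else -(10**9)),
            i,
        ),
    )
    seen: set[tuple[int, int]] = set()
    kept_idx: set[int] = set()
    rejected: list[tuple[OccurrenceRecord, str]] = []
    for i in order:
        rec = occ.records[i]
        cell = grid.cell_of(rec.x, rec.y)
        if cell in seen:
            rejected.append((rec, "duplicate_cell"))
        else:
            seen.add(cell)
            kept_idx.add(i)
    kept = OccurrenceSet([occ.records[i] for i in sorted(kept_idx)])
    return FilterReport(kept=kept, rejected=rejected)


def filter_occurrences(
    occ: OccurrenceSet,
    range_polygon: BaseGeometry,
    elevation: Grid2D,
    elev_min: float,
    elev_max: float,
    elev_buffer: float = 100.0,
    landcover: Grid2D | None = None,
    allowed_classes: Iterable[int] | None = None,
) -> FilterReport:
    """Apply the three exclusion rules in order; first failure is recorded.

    Rules: (1) outside the range polygon (points off the raster extent also
    fail here); (2) elevation outside [elev_min - buffer, elev_max + buffer]
    inclusive, using the record's own elevation when present and the
    elevation layer at its cell otherwise; (3) land-cover class at the
    record's cell not in ``allowed_classes`` (skipped when no land-cover
    layer is given).
    """
    if elev_min > elev_max:
        raise ValueError("elev_min must not exceed elev_max")
    allowed = set(allowed_classes) if allowed_classes is not None else None
    lo, hi = elev_min - elev_buffer, elev_max + elev_buffer
    kept: list[OccurrenceRecord] = []
    rejected: list[tuple[OccurrenceRecord, str]] = []
    for rec in occ.records:
        row, col = elevation.cell_of(rec.x, rec.y)
        on_grid = elevation.contains_cell(row, col)
        if not on_grid or not range_polygon.intersects(Point(rec.x, rec.y)):
            rejected.append((rec, "outside_polygon"))
            continue
        elev = rec.elevation
        if elev is None:
            elev = elevation.value_at(rec.x, rec.y)
        if not np.isfinite(elev) or not (lo <= elev <= hi):
            rejected.append((rec, "elevation_out_of_range"))
            continue
        if landcover is not None and allowed is not None:
            code = landcover.value_at(rec.x, rec.y)
            if not np.isfinite(code) or int(code) not in allowed:
                rejected.append((rec, "landcover_mismatch"))
                continue
        kept.append(rec)
    return FilterReport(kept=OccurrenceSet(kept), rejected=rejected)


@dataclass
class PseudoAbsenceSet:
    """One background sample: cell-centre points drawn without replacement."""

    set_id: int
    points: np.ndarray  # (n, 2) of x, y
    cells: list[tuple[int, int]]
    seed: int


def sample_pseudo_absences(
    valid_mask: Grid2D,
    n: int,
    presence_cells: Sequence[tuple[int, int]],
    n_sets: int = 3,
    seed: int = 0,
) -> list[PseudoAbsenceSet]:
    """Draw ``n_sets`` independent background sets of ``n`` cell centres.

    ``valid_mask`` marks the study grid (its nodata mask excludes cells);
    presence cells are never drawn. Each set is a uniform draw without
    replacement, reproducible from (seed, set_id).
    """
    rows, cols = valid_mask.shape
    eligible = ~valid_mask.nodata_mask.copy()
    for r, c in presence_cells:
        if 0 <= r < rows and 0 <= c < cols:
            eligible[r, c] = False
    flat = np.flatnonzero(eligible.ravel())
    if n > flat.size:
        raise ValueError(f"requested {n} pseudo-absences but only {flat.size} cells available")
    sets = []
    for set_id in range(n_sets):
        rng = np.random.default_rng([seed, set_id])
        chosen = rng.choice(flat, size=n, replace=False)
        cells = [(int(i // cols), int(i % cols)) for i in chosen]
        pts = np.array([valid_mask.cell_center(r, c) for r, c in cells]).reshape(-1, 2)
        sets.append(PseudoAbsenceSet(set_id=set_id, points=pts, cells=cells, seed=seed))
    return sets
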