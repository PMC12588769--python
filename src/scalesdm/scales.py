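"""Characteristic-scale selection and collinearity screening.

Each variable's "scale of effect" is the moving-window radius at which it
best discriminates presence from background locations, found by a Welch
two-sample t-test of the focally aggregated values at presence vs background
points for each candidate radius; only radii with p < 0.05 are eligible and
the radius with the smallest p wins (smaller radius on ties). Variables
with no significant radius are excluded. The surviving single-scale layers
are then screened for collinearity: a greedy pass in ascending order of the
chosen p keeps a variable only if its Pearson correlation with every
already-kept variable is at most the threshold (|r| <= 0.7 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .focal import MultiScaleLayer
from .grids import Grid2D

__all__ = [
    "ScaleProfile",
    "ScreenResult",
    "welch_t_test",
    "extract_at_cells",
    "select_characteristic_scales",
    "correlation_screen",
    "profiles_table",
]

SIGNIFICANCE_DEFAULT = 0.05


@dataclass
class ScaleProfile:
    """Per-variable test results across radii and the chosen scale."""

    variable: str
    tests: dict[float, tuple[float, float]] = field(default_factory=dict)  # radius -> (t, p)
    chosen_radius_km: float | None = None
    chosen_p: float | None = None

    @property
    def excluded(self) -> bool:
        return self.chosen_radius_km is None


@dataclass
class ScreenResult:
    retained: list[str]
    dropped: list[dict] = field(default_factory=list)  # {variable, against, r}


def welch_t_test(sample_a, sample_b) -> tuple[float, float]:
    """Two-sided Welch (unequal-variance) t-test.

    Returns (t, p). Two identical constant samples give (0, 1); samples
    with fewer than two finite values raise.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 finite values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return np.inf, 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def extract_at_cells(grid: Grid2D, cells) -> np.ndarray:
    """Layer values at (row, col) cells; NaN for off-grid or masked cells."""
    out = np.full(len(cells), np.nan)
    for i, (r, c) in enumerate(cells):
        if grid.contains_cell(r, c) and not grid.nodata_mask[r, c]:
            out[i] = grid.values[r, c]
    return out


def select_characteristic_scales(
    multiscale_layers: list[MultiScaleLayer],
    presence_cells,
    background_cells,
    significance: float = SIGNIFICANCE_DEFAULT,
) -> list[ScaleProfile]:
    """One :class:`ScaleProfile` per variable.

    For each (variable, radius) layer, values are extracted at presence and
    background cells (NaNs from masked cells dropped) and Welch-tested. The
    chosen radius minimises p among radii with p < ``significance``; ties go
    to the smaller radius; a variable with no significant radius is excluded
    (``chosen_radius_km is None``). A variable constant at all points yields
    p = 1 everywhere and is excluded.
    """
    by_var: dict[str, list[MultiScaleLayer]] = {}
    for layer in multiscale_layers:
        by_var.setdefault(layer.base_name, []).append(layer)

    profiles = []
    for var in by_var:
        profile = ScaleProfile(variable=var)
        for layer in sorted(by_var[var], key=lambda l: l.radius_km):
            pres = extract_at_cells(layer.grid, presence_cells)
            back = extract_at_cells(layer.grid, background_cells)
            pres, back = pres[np.isfinite(pres)], back[np.isfinite(back)]
            if pres.size < 2 or back.size < 2:
                t, p = 0.0, 1.0
            else:
                t, p = welch_t_test(pres, back)
            profile.tests[layer.radius_km] = (t, p)
        significant = [
            (p, radius) for radius, (_, p) in profile.tests.items() if p < significance
        ]
        if significant:
            p_best, radius_best = min(significant)  # ties -> smaller radius
            profile.chosen_radius_km = radius_best
            profile.chosen_p = p_best
        profiles.append(profile)
    return profiles


def correlation_screen(
    chosen_layers: dict[str, Grid2D],
    profiles: list[ScaleProfile],
    threshold: float = 0.7,
    sample_cells: int = 50_000,
    seed: int = 0,
) -> ScreenResult:
    """Greedy collinearity screen on the chosen-scale layers.

    Variables are visited in ascending order of their chosen p (name as tie
    break); a candidate is retained iff |Pearson r| <= ``threshold`` against
    every already-retained variable, computed over a common seeded sample of
    at most ``sample_cells`` cells valid in all layers. Dropped entries cite
    the retained partner and the offending r.
    """
    p_of = {pr.variable: pr.chosen_p for pr in profiles if not pr.excluded}
    candidates = [v for v in p_of if v in chosen_layers]
    if len(candidates) < 2:
        return ScreenResult(retained=sorted(candidates, key=lambda v: (p_of[v], v)))
    order = sorted(candidates, key=lambda v: (p_of[v], v))

    common_valid = ~np.logical_or.reduce(
        [chosen_layers[v].nodata_mask for v in order]
    )
    idx = np.flatnonzero(common_valid.ravel())
    if idx.size > sample_cells:
        rng = np.random.default_rng(seed)
        idx = rng.choice(idx, size=sample_cells, replace=False)
    data = {v: chosen_layers[v].values.ravel()[idx] for v in order}

    retained: list[str] = []
    dropped: list[dict] = []
    for var in order:
        conflict = None
        for kept in retained:
            if np.std(data[var]) == 0 or np.std(data[kept]) == 0:
                r = 0.0
            else:
                r = float(np.corrcoef(data[var], data[kept])[0, 1])
            if abs(r) > threshold:
                conflict = {"variable": var, "against": kept, "r": r}
                break
        if conflict is None:
            retained.append(var)
        else:
            dropped.append(conflict)
    return ScreenResult(retained=retained, dropped=dropped)


def profiles_table(profiles: list[ScaleProfile], retained: list[str] | None = None) -> pd.DataFrame:
    """Long-format table: variable, radius, t, p, chosen flag, retained flag."""
    rows = []
    for pr in profiles:
        for radius, (t, p) in sorted(pr.tests.items()):
            rows.append(
                {
                    "variable": pr.variable,
                    "radius_km": radius,
                    "t": t,
                    "p": p,
                    "chosen": radius == pr.chosen_radius_km,
                    "retained": (retained is None or pr.variable in retained)
                    and not pr.excluded,
                }
            )
    return pd.DataFrame(rows)
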