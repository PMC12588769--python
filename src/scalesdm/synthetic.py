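"""Synthetic landscapes with known habitat-suitability ground truth.

The generator emulates the statistical structure a montane-pheasant
distribution analysis assumes, without any real geography: spatially
autocorrelated climate fields coupled to an elevation gradient through a
lapse rate, derived topography (slope, aspect, northness, terrain
ruggedness), a patchy categorical land cover (forest / cropland / other)
with cropland concentrated at low elevation, and a human-footprint-like
disturbance index. A known ("true") suitability surface is a logistic
function of focally aggregated variables — unimodal in a warm-month
temperature and in terrain ruggedness, increasing in forest fraction — each
evaluated at a known radius, so downstream scale selection and model fitting
can be validated against recoverable ground truth.

Future scenario stacks apply a stated warming offset to temperature layers,
a multiplier to precipitation layers, and convert a stated fraction of
forest to cropland, preferentially at low elevation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import ndimage

from .focal import focal_fraction, focal_mean
from .grids import Grid2D, LayerStack
from .occurrences import OccurrenceRecord, OccurrenceSet

__all__ = [
    "SyntheticTruth",
    "ScenarioSpec",
    "FOREST",
    "CROPLAND",
    "OTHER",
    "TEMPERATURE_LAYERS",
    "PRECIPITATION_LAYERS",
    "generate_autocorrelated_field",
    "generate_landscape",
    "derive_topography",
    "true_suitability",
    "sample_occurrences",
    "generate_future_stack",
]

# land-cover class codes and pinned landscape prevalences
FOREST, CROPLAND, OTHER = 1, 2, 3
FOREST_PREVALENCE = 0.45
CROPLAND_PREVALENCE = 0.25

# layer families used by scenario construction
TEMPERATURE_LAYERS = ("annualtem", "tem_warmmon", "tem_coldmon")
PRECIPITATION_LAYERS = ("annualprec", "prec_wetmon", "prec_drymon")


@dataclass
class SyntheticTruth:
    """Generating parameters of the true suitability surface.

    ``true_radii`` gives the radius (km) at which each variable is focally
    aggregated before its response is evaluated; ``response_params`` maps
    each variable to either ``{"unimodal": (optimum, width)}`` (a negative
    quadratic in the aggregated variable) or ``{"monotone": slope}`` /
    ``{"monotone": (slope, center)}`` (a linear term, optionally centred).
    Defaults encode a warm-month temperature optimum of 15 °C at a 6 km
    scale, a strong positive forest-fraction effect at 7 km, and a
    ruggedness optimum at 8 km.
    """

    true_radii: dict[str, float] = field(
        default_factory=lambda: {"forest": 7.0, "tem_warmmon": 6.0, "tri": 8.0}
    )
    response_params: dict[str, dict] = field(
        default_factory=lambda: {
            "tem_warmmon": {"unimodal": (15.0, 7.0)},
            "forest": {"monotone": (30.0, 0.45)},
            "tri": {"unimodal": (60.0, 120.0)},
        }
    )
    intercept: float = -0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for var, params in self.response_params.items():
            if "unimodal" in params:
                _, width = params["unimodal"]
                if width <= 0:
                    raise ValueError(f"unimodal width for {var!r} must be > 0")


@dataclass
class ScenarioSpec:
    """One future scenario realization (pathway x period x climate model)."""

    label: str
    period: str
    gcm_label: str = "GCM0"
    warming_offset: float = 0.0
    precip_factor: float = 1.0
    forest_to_crop_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.forest_to_crop_rate <= 1.0):
            raise ValueError("forest_to_crop_rate must be in [0, 1]")
        if self.precip_factor <= 0:
            raise ValueError("precip_factor must be > 0")


def generate_autocorrelated_field(
    rows: int,
    cols: int,
    correlation_length_cells: float,
    seed: int | np.random.SeedSequence,
) -> Grid2D:
    """Zero-mean, unit-variance field with the given correlation length.

    Seeded white noise smoothed by an isotropic Gaussian kernel whose sigma
    is the correlation length (in cells), then standardised exactly to mean
    0 / sd 1. Length 0 is pure white noise. Smoothing wraps toroidally so
    the field is stationary with no edge attenuation.
    """
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    if correlation_length_cells < 0:
        raise ValueError("correlation length must be >= 0")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((rows, cols))
    if correlation_length_cells > 0:
        noise = ndimage.gaussian_filter(noise, sigma=correlation_length_cells, mode="wrap")
    noise = noise - noise.mean()
    sd = noise.std()
    if sd > 0:
        noise = noise / sd
    return Grid2D(noise)


def _fields(seed: int, rows: int, cols: int, specs: Mapping[str, float]) -> dict[str, np.ndarray]:
    """One independent autocorrelated field per name, fanned out from seed."""
    children = np.random.SeedSequence(seed).spawn(len(specs))
    return {
        name: generate_autocorrelated_field(rows, cols, length, child).values
        for (name, length), child in zip(specs.items(), children)
    }


def derive_topography(elevation: Grid2D) -> LayerStack:
    """Slope, aspect, northness and terrain ruggedness from an elevation grid.

    Slope and aspect use Horn's 8-neighbour finite differences; aspect is
    degrees clockwise from north (downslope direction), defined as 0 on flat
    cells with northness forced to 0 there. Northness = sin(slope)*cos(aspect).
    The terrain ruggedness index (tri) is the mean absolute elevation
    difference between a cell and its 8 neighbours. Edge cells and cells
    whose 3x3 window touches nodata are masked.
    """
    valid = ~elevation.nodata_mask
    if valid.sum() == 0:
        raise ValueError("elevation grid is fully masked")
    z = np.where(valid, elevation.values.astype(float), np.nan)
    rows, cols = z.shape
    if rows < 3 or cols < 3:
        raise ValueError("need at least a 3x3 grid to derive topography")
    cell = elevation.cell_size

    # 3x3 window views: w[dr][dc] is z shifted so index (i,j) sees neighbour
    # (i+dr-1, j+dc-1); interior cells only.
    w = {}
    for dr in range(3):
        for dc in range(3):
            w[(dr, dc)] = z[dr : rows - 2 + dr, dc : cols - 2 + dc]
    a, b, c = w[(0, 0)], w[(0, 1)], w[(0, 2)]
    d, e, f = w[(1, 0)], w[(1, 1)], w[(1, 2)]
    g, h, i = w[(2, 0)], w[(2, 1)], w[(2, 2)]

    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8 * cell)  # east
    dzdy = ((a + 2 * b + c) - (g + 2 * h + i)) / (8 * cell)  # north
    slope_rad = np.arctan(np.hypot(dzdx, dzdy))
    flat = (dzdx == 0) & (dzdy == 0)
    aspect_rad = np.where(
        flat, 0.0, np.mod(np.arctan2(-dzdx, -dzdy), 2 * np.pi)
    )
    northness = np.where(flat, 0.0, np.sin(slope_rad) * np.cos(aspect_rad))

    neigh = [a, b, c, d, f, g, h, i]
    tri = sum(np.abs(n - e) for n in neigh) / 8.0

    interior_invalid = np.isnan(slope_rad) | np.isnan(tri)

    def full(interior: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        out = np.full((rows, cols), np.nan)
        out[1:-1, 1:-1] = np.where(interior_invalid, np.nan, interior)
        mask = np.ones((rows, cols), dtype=bool)
        mask[1:-1, 1:-1] = interior_invalid
        return out, mask

    stack = LayerStack()
    for name, interior in [
        ("slope", np.degrees(slope_rad)),
        ("aspect", np.degrees(aspect_rad)),
        ("northness", northness),
        ("tri", tri),
    ]:
        vals, mask = full(interior)
        stack.add(name, elevation.with_values(np.nan_to_num(vals), mask), "continuous")
    return stack


def generate_landscape(
    rows: int, cols: int, cell_size: float, truth: SyntheticTruth
) -> LayerStack:
    """Full predictor stack with the structure the analysis assumes.

    Contains elevation plus derived topography, three temperature-like and
    three precipitation-like continuous layers (temperature coupled to
    elevation through a 6.5 °C/km lapse rate; warm- and cold-month layers
    are offsets of the annual mean, so at least one pair is collinear with
    |r| > 0.7), two seasonality layers independent of the truth (so at
    least one variable shows no presence/background contrast), a categorical
    land cover with classes forest/cropland/other (cropland concentrated at
    low elevation), and a footprint-like disturbance index.
    """
    max_radius_cells = max(
        (r * 1000.0 / cell_size for r in truth.true_radii.values()), default=0.0
    )
    if min(rows, cols) <= 2 * max_radius_cells:
        raise ValueError(
            "grid too small to support the largest true radius "
            f"({max_radius_cells:g} cells on a {rows}x{cols} grid)"
        )

    f = _fields(
        truth.seed,
        rows,
        cols,
        {
            "elev": 10.0,
            "annualtem": 8.0,
            "tem_warm": 6.0,
            "tem_cold": 6.0,
            "temvar": 8.0,
            "annualprec": 10.0,
            "prec_wet": 8.0,
            "prec_dry": 8.0,
            "prec_var": 8.0,
            "lc_forest": 1.0,
            "lc_crop": 1.5,
            "footprint": 4.0,
        },
    )

    elev = 2200.0 + 1000.0 * f["elev"]
    elev = np.maximum(elev, 50.0)
    z_elev = (elev - elev.mean()) / elev.std()

    annualtem = 20.0 - 6.5 * elev / 1000.0 + 1.2 * f["annualtem"]
    stack = LayerStack()

    def grid(vals: np.ndarray) -> Grid2D:
        return Grid2D(vals, cell_size=cell_size, origin=(0.0, rows * cell_size))

    stack.add("elevation", grid(elev), "continuous")
    topo = derive_topography(stack["elevation"])
    for name in topo.names:
        stack.add(name, topo[name], "continuous")

    stack.add("annualtem", grid(annualtem), "continuous")
    stack.add("temvar", grid(8.0 + 2.0 * f["temvar"]), "continuous")
    stack.add("tem_warmmon", grid(annualtem + 10.0 + 0.8 * f["tem_warm"]), "continuous")
    stack.add("tem_coldmon", grid(annualtem - 10.0 + 1.5 * f["tem_cold"]), "continuous")

    annualprec = np.maximum(1200.0 + 350.0 * f["annualprec"], 50.0)
    stack.add("annualprec", grid(annualprec), "continuous")
    stack.add(
        "prec_wetmon", grid(np.maximum(0.22 * annualprec + 40.0 * f["prec_wet"], 0.0)), "continuous"
    )
    stack.add(
        "prec_drymon", grid(np.maximum(20.0 + 12.0 * f["prec_dry"], 0.0)), "continuous"
    )
    stack.add("prec_var", grid(70.0 + 15.0 * f["prec_var"]), "continuous")

    # land cover with quantile-pinned prevalences: 25% cropland (biased to
    # low elevation), 45% forest, 30% other. Pinning keeps the forest
    # fraction's landscape mean at the truth's response centre every seed.
    crop_score = 0.3 * (-z_elev) + f["lc_crop"]
    crop = crop_score > np.quantile(crop_score, 1.0 - CROPLAND_PREVALENCE)
    forest_field = f["lc_forest"]
    thr = np.quantile(
        forest_field[~crop], 1.0 - FOREST_PREVALENCE / (1.0 - CROPLAND_PREVALENCE)
    )
    forest = ~crop & (forest_field > thr)
    landcover = np.where(forest, FOREST, np.where(crop, CROPLAND, OTHER))
    stack.add("landcover", grid(landcover.astype(np.int64)), "categorical")

    footprint = np.clip(20.0 - 8.0 * z_elev + 6.0 * f["footprint"], 0.0, 50.0)
    stack.add("footprint", grid(footprint), "continuous")
    return stack


def _aggregated_variable(stack: LayerStack, var: str, radius_km: float) -> Grid2D:
    """Variable focally aggregated at the given radius.

    ``forest`` and ``cropland`` are class fractions of the ``landcover``
    layer; any other name is the focal mean of the continuous layer.
    """
    cell_size = stack.reference.cell_size
    radius_cells = radius_km * 1000.0 / cell_size
    if var in ("forest", "cropland"):
        if "landcover" not in stack:
            raise KeyError("stack has no landcover layer for class fractions")
        code = FOREST if var == "forest" else CROPLAND
        return focal_fraction(stack["landcover"], code, radius_cells)
    if var not in stack:
        raise KeyError(f"stack has no layer {var!r}")
    return focal_mean(stack[var], radius_cells)


def true_suitability(stack: LayerStack, truth: SyntheticTruth) -> Grid2D:
    """Logistic suitability surface from focally aggregated variables.

    Each variable named in ``truth.response_params`` is aggregated at its
    true radius, then contributes either a negative quadratic
    ``-((x - optimum)/width)**2`` or a linear ``slope * x`` term; the sum
    plus the intercept is passed through a logistic, giving values in [0, 1].
    """
    ref = stack.reference
    eta = np.full(ref.shape, float(truth.intercept))
    mask = np.zeros(ref.shape, dtype=bool)
    for var, params in truth.response_params.items():
        radius = truth.true_radii.get(var, 0.0)
        agg = _aggregated_variable(stack, var, radius)
        x = agg.values
        if "unimodal" in params:
            opt, width = params["unimodal"]
            term = -(((x - opt) / width) ** 2)
        elif "monotone" in params:
            mono = params["monotone"]
            if np.isscalar(mono):
                term = mono * x
            else:
                slope, center = mono
                term = slope * (x - center)
        else:
            raise ValueError(f"response for {var!r} must be unimodal or monotone")
        eta = eta + np.where(agg.nodata_mask, 0.0, term)
        mask |= agg.nodata_mask
    suit = 1.0 / (1.0 + np.exp(-eta))
    suit = np.where(mask, np.nan, suit)
    return ref.with_values(np.nan_to_num(suit), mask)


def sample_occurrences(
    suitability: Grid2D,
    n: int,
    seed: int,
    elevation: Grid2D | None = None,
    year: int | None = None,
) -> OccurrenceSet:
    """Presence points drawn with probability proportional to suitability.

    Cells are drawn with replacement (several records may share a cell, as
    in real presence archives before thinning); each record sits at its
    cell's centre, with elevation filled from the elevation layer when given.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    p = np.where(suitability.nodata_mask, 0.0, suitability.values).astype(float)
    if np.any((p < -1e-9) | (p > 1 + 1e-9)):
        raise ValueError("suitability must lie in [0, 1]")
    total = p.sum()
    if total <= 0:
        raise ValueError("cannot sample occurrences from an all-zero suitability")
    rng = np.random.default_rng(seed)
    flat = rng.choice(p.size, size=n, replace=True, p=p.ravel() / total)
    records = []
    for idx in flat:
        r, c = divmod(int(idx), suitability.cols)
        x, y = suitability.cell_center(r, c)
        elev = None
        if elevation is not None:
            v = elevation.values[r, c]
            elev = float(v) if not elevation.nodata_mask[r, c] else None
        records.append(OccurrenceRecord(x=x, y=y, elevation=elev, year=year))
    return OccurrenceSet(records)


def generate_future_stack(stack: LayerStack, spec: ScenarioSpec) -> LayerStack:
    """Scenario stack: warming offset, precipitation scaling, forest loss.

    Temperature-like layers are shifted by ``warming_offset``;
    precipitation-like layers are multiplied by ``precip_factor``; a
    ``forest_to_crop_rate`` fraction of forest cells (rounded to the nearest
    count) is re-coded cropland, drawn without replacement with weights
    proportional to the inverse elevation rank so low-elevation forest is
    converted first. Topography and all other layers are untouched.
    """
    out = stack.copy()
    for name in TEMPERATURE_LAYERS:
        if name in out and spec.warming_offset != 0.0:
            g = out[name]
            out.layers[name] = g.with_values(g.values + spec.warming_offset)
    for name in PRECIPITATION_LAYERS:
        if name in out and spec.precip_factor != 1.0:
            g = out[name]
            out.layers[name] = g.with_values(g.values * spec.precip_factor)
    if spec.forest_to_crop_rate > 0 and "landcover" in out:
        lc = out["landcover"]
        forest_idx = np.flatnonzero((lc.values == FOREST).ravel() & ~lc.nodata_mask.ravel())
        k = int(round(spec.forest_to_crop_rate * forest_idx.size))
        if k > 0:
            if "elevation" in out:
                elev = out["elevation"].values.ravel()[forest_idx]
                # rank 1 = lowest elevation gets the largest weight
                ranks = np.empty(forest_idx.size, dtype=float)
                ranks[np.argsort(elev, kind="stable")] = np.arange(1, forest_idx.size + 1)
                weights = 1.0 / ranks
            else:
                weights = np.ones(forest_idx.size)
            weights = weights / weights.sum()
            rng = np.random.default_rng(spec.seed)
            chosen = rng.choice(forest_idx, size=k, replace=False, p=weights)
            vals = lc.values.copy()
            vals.ravel()[chosen] = CROPLAND
            out.layers["landcover"] = lc.with_values(vals)
    return out
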