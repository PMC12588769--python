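"""End-to-end orchestration: one seeded config in, a reproducible bundle out.

Chains synthetic generation (or user files) through occurrence prep,
multi-scale construction, scale selection, collinearity screening, ensemble
fitting and cross-validation, current mapping and thresholding, scenario
projection with climate-model averaging, dispersal variants, time-step maps,
change accounting, and range-shift diagnostics. Every stochastic step is
fanned out deterministically from the single config seed, so re-running a
config reproduces all CSV outputs bit-identically.
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import MultiPoint

from . import __version__ as _version
from .ensemble import (
    BaseLearnerSpec,
    auc,
    boyce_index,
    build_ensemble,
    cross_validate,
    response_curve,
    runs_table,
    tss_max,
    variable_importance,
)
from .focal import build_multiscale_stack
from .grids import LayerStack
from .occurrences import OccurrenceSet, filter_occurrences, sample_pseudo_absences, thin_occurrences
from .projection import (
    apply_dispersal_mask,
    average_gcms,
    bin_suitability,
    binarize,
    change_metrics,
    extract_features,
    project_suitability,
    resilient_area,
    time_step_map,
)
from .ranges import elevation_shift, mcp, mcp_overlap
from .scales import correlation_screen, profiles_table, select_characteristic_scales
from .synthetic import (
    CROPLAND,
    FOREST,
    OTHER,
    ScenarioSpec,
    SyntheticTruth,
    generate_future_stack,
    generate_landscape,
    sample_occurrences,
    true_suitability,
)

__all__ = ["RunConfig", "RunManifest", "validate_config", "run_pipeline", "DEFAULT_SCENARIOS"]

# synthetic scenario analogs: per pathway and period, a warming offset (°C),
# a precipitation multiplier, and a cumulative forest-to-cropland rate;
# three climate-model realizations jitter the climate terms.
DEFAULT_SCENARIOS = {
    "SSP126": {"2070": (1.5, 1.03, 0.05), "2100": (1.8, 1.05, 0.05)},
    "SSP370": {"2070": (3.0, 1.05, 0.15), "2100": (4.5, 1.08, 0.30)},
    "SSP585": {"2070": (4.0, 1.07, 0.20), "2100": (6.0, 1.10, 0.40)},
}
GCM_DELTAS = {"GCM-A": (-0.5, 0.97), "GCM-B": (0.0, 1.0), "GCM-C": (0.5, 1.03)}


@dataclass
class RunConfig:
    """Everything a pipeline run needs; ``seed`` is mandatory."""

    seed: int
    output_dir: str = "scalesdm_run"
    mode: str = "synthetic"  # or "files"
    # synthetic world
    rows: int = 64
    cols: int = 64
    cell_size: float = 1000.0
    n_occurrences: int = 150
    # files mode
    stack_dir: str | None = None
    occurrences_csv: str | None = None
    # occurrence cleaning
    elev_min: float = 500.0
    elev_max: float = 4500.0
    elev_buffer: float = 100.0
    allowed_landcover: tuple[int, ...] = (FOREST, OTHER)
    # multi-scale and selection
    radii_km: tuple[float, ...] = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10)
    significance: float = 0.05
    correlation_threshold: float = 0.7
    # background and modeling
    pa_sets: int = 3
    pa_n: int = 2000
    algorithms: tuple[str, ...] = ("GLM", "GAM", "MAXENT_LIKE", "RF", "XGB")
    k: int = 5
    repeats: int = 3
    auc_cutoff: float = 0.7
    # scenarios and dispersal
    scenarios: dict = field(default_factory=lambda: DEFAULT_SCENARIOS)
    dispersal_buffer_km: float = 10.0

    def __post_init__(self) -> None:
        # YAML round-trips tuples as lists; normalise nested scenario triples
        self.scenarios = {
            label: {period: tuple(v) for period, v in periods.items()}
            for label, periods in self.scenarios.items()
        }

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("allowed_landcover", "radii_km", "algorithms"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class RunManifest:
    config: dict
    version: str
    stage_seconds: dict[str, float] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)  # relpath -> sha256

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(
                {
                    "config": self.config,
                    "version": self.version,
                    "stage_seconds": self.stage_seconds,
                    "outputs": self.outputs,
                },
                sort_keys=True,
            )
        )


def validate_config(config: RunConfig) -> list[dict]:
    """Errors and warnings as data; errors block :func:`run_pipeline`."""
    findings = []

    def err(msg):
        findings.append({"level": "error", "message": msg})

    def warn(msg):
        findings.append({"level": "warning", "message": msg})

    if config.seed is None:
        err("seed is mandatory")
    if not (0 < config.significance < 1):
        err(f"significance {config.significance} outside (0, 1)")
    if not (0 < config.correlation_threshold <= 1):
        err(f"correlation threshold {config.correlation_threshold} outside (0, 1]")
    if not (0 <= config.auc_cutoff < 1):
        err(f"AUC cutoff {config.auc_cutoff} outside [0, 1)")
    if config.mode not in ("synthetic", "files"):
        err(f"unknown mode {config.mode!r}")
    if config.mode == "files" and not (config.stack_dir and config.occurrences_csv):
        err("files mode requires stack_dir and occurrences_csv")
    if config.pa_sets < 1 or config.pa_n < 1:
        err("pa_sets and pa_n must be positive")
    if list(config.radii_km) != sorted(config.radii_km):
        warn("radii not ascending; they will be sorted")
    unknown = set(config.algorithms) - {"GLM", "GAM", "MAXENT_LIKE", "RF", "XGB"}
    if unknown:
        err(f"unknown algorithms {sorted(unknown)}")
    return findings


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False)


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the full analysis and write the output bundle.

    Raises at the first failing stage with the stage name in the message.
    """
    findings = validate_config(config)
    errors = [f for f in findings if f["level"] == "error"]
    if errors:
        raise ValueError("invalid config: " + "; ".join(f["message"] for f in errors))
    radii = tuple(sorted(config.radii_km))

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=asdict(config), version=_version)
    clock = time.perf_counter
    stage_t0 = clock()

    def tick(stage: str):
        nonlocal stage_t0
        manifest.stage_seconds[stage] = round(clock() - stage_t0, 3)
        stage_t0 = clock()

    # -- stage: inputs ------------------------------------------------------
    if config.mode == "synthetic":
        truth = SyntheticTruth(seed=config.seed)
        stack = generate_landscape(config.rows, config.cols, config.cell_size, truth)
        suit_true = true_suitability(stack, truth)
        occ_raw = sample_occurrences(
            suit_true, config.n_occurrences, seed=config.seed + 1,
            elevation=stack["elevation"], year=2020,
        )
    else:
        truth = None
        stack = LayerStack.from_dir(config.stack_dir)
        occ_raw = OccurrenceSet.from_csv(config.occurrences_csv)
    ref = stack.reference
    tick("inputs")

    # -- stage: occurrence prep --------------------------------------------
    hull = MultiPoint([tuple(p) for p in occ_raw.coordinates()]).convex_hull
    range_polygon = hull.buffer(5 * ref.cell_size)
    filt = filter_occurrences(
        occ_raw,
        range_polygon,
        stack["elevation"],
        config.elev_min,
        config.elev_max,
        elev_buffer=config.elev_buffer,
        landcover=stack["landcover"] if "landcover" in stack else None,
        allowed_classes=config.allowed_landcover,
    )
    thinned = thin_occurrences(filt.kept, ref)
    occ = thinned.kept
    if len(occ) < max(20, config.k):
        raise RuntimeError(f"occurrence prep left only {len(occ)} usable presences")
    occ.to_csv(out / "occurrences_kept.csv")
    rej = pd.DataFrame(
        [
            {"x": r.x, "y": r.y, "reason": reason}
            for r, reason in filt.rejected + thinned.rejected
        ],
        columns=["x", "y", "reason"],
    )
    _write_csv(rej, out / "occurrences_rejected.csv")
    presence_cells = occ.cells(ref)
    tick("occurrence_prep")

    # -- stage: multi-scale build ------------------------------------------
    modeling = LayerStack()
    for name in stack.names:
        if name == "aspect":  # circular; northness carries the orientation signal
            continue
        modeling.add(name, stack[name], stack.kinds[name])
    msl = build_multiscale_stack(
        modeling,
        list(radii),
        categorical_classes={"landcover": {"forest": FOREST, "cropland": CROPLAND}},
    )
    tick("multiscale")

    # -- stage: background sampling ----------------------------------------
    pa_sets = sample_pseudo_absences(
        ref, config.pa_n, presence_cells, n_sets=config.pa_sets, seed=config.seed + 2
    )
    tick("pseudo_absences")

    # -- stage: scale selection and screening ------------------------------
    profiles = select_characteristic_scales(
        msl, presence_cells, pa_sets[0].cells, significance=config.significance
    )
    chosen_layers = {
        pr.variable: next(
            l.grid
            for l in msl
            if l.base_name == pr.variable and l.radius_km == pr.chosen_radius_km
        )
        for pr in profiles
        if not pr.excluded
    }
    screen = correlation_screen(
        chosen_layers,
        profiles,
        threshold=config.correlation_threshold,
        seed=config.seed + 3,
    )
    _write_csv(profiles_table(profiles, screen.retained), out / "scale_profiles.csv")
    _write_csv(
        pd.DataFrame(screen.dropped, columns=["variable", "against", "r"]),
        out / "screen_dropped.csv",
    )
    chosen_radii = {
        pr.variable: pr.chosen_radius_km
        for pr in profiles
        if not pr.excluded and pr.variable in screen.retained
    }
    if not chosen_radii:
        raise RuntimeError("scale selection retained no variables")
    tick("scale_selection")

    # -- stage: features and cross-validated ensemble ----------------------
    pres_X, pres_ok = extract_features(stack, chosen_radii, presence_cells)
    pres_X = pres_X.loc[pres_ok].reset_index(drop=True)
    bg_frames = []
    for pa in pa_sets:
        bg_X, bg_ok = extract_features(stack, chosen_radii, pa.cells)
        bg_frames.append(bg_X.loc[bg_ok].reset_index(drop=True))
    specs = [BaseLearnerSpec(a) for a in config.algorithms]
    runs = cross_validate(
        pres_X, bg_frames, specs, k=config.k, repeats=config.repeats, seed=config.seed + 4
    )
    _write_csv(runs_table(runs), out / "model_runs.csv")
    model = build_ensemble(runs, pres_X, bg_frames[0], auc_cutoff=config.auc_cutoff)
    ens_pos = model.predict(pres_X)
    ens_neg = model.predict(bg_frames[0])
    ens_tss, _ = tss_max(ens_pos, ens_neg)
    summary = pd.DataFrame(
        [
            {
                "n_members": len(model.members),
                "n_runs": len(runs),
                "auc": auc(ens_pos, ens_neg),
                "tss": ens_tss,
                "boyce": boyce_index(ens_pos, ens_neg),
                "threshold_maxsss": model.threshold_maxsss,
            }
        ]
    )
    _write_csv(summary, out / "ensemble_summary.csv")
    tick("ensemble")

    # -- stage: interpretation ---------------------------------------------
    eval_X = pd.concat([pres_X, bg_frames[0]], ignore_index=True)
    importances = {
        var: variable_importance(model, eval_X, var, seed=config.seed + 5)
        for var in model.variable_set
    }
    imp_df = pd.DataFrame(
        sorted(importances.items(), key=lambda kv: -kv[1]),
        columns=["variable", "importance"],
    )
    _write_csv(imp_df, out / "importances.csv")
    curves = []
    for var in imp_df["variable"].head(3):
        cc = response_curve(model, eval_X, var)
        cc.insert(0, "variable", var)
        curves.append(cc)
    _write_csv(pd.concat(curves, ignore_index=True), out / "response_curves.csv")
    tick("interpretation")

    # -- stage: current map and threshold ----------------------------------
    current_suit = project_suitability(model, stack, chosen_radii)
    current_suit.to_ascii(out / "suitability_current.asc")
    bins = bin_suitability(current_suit)
    bins.insert(0, "period", "current")
    bins.insert(0, "scenario", "current")
    bin_tables = [bins]
    current_bin = binarize(current_suit, model.threshold_maxsss)
    current_bin.grid.to_ascii(out / "binary_current.asc")
    tick("current_map")

    # -- stage: scenario projection and change accounting ------------------
    change_rows = {"perfect": [], "limited": []}
    timestep_rows = []
    scen_index = 0
    for scen_label, periods in config.scenarios.items():
        period_binaries = {"perfect": [current_bin], "limited": [current_bin]}
        for period_label, (warm, pfac, rate) in periods.items():
            scen_index += 1
            land_spec = ScenarioSpec(
                label=scen_label, period=period_label, warming_offset=0.0,
                precip_factor=1.0, forest_to_crop_rate=rate,
                seed=config.seed + 100 + scen_index,
            )
            land_stack = generate_future_stack(stack, land_spec)
            gcm_maps = []
            for gcm, (dwarm, dp) in GCM_DELTAS.items():
                clim_spec = ScenarioSpec(
                    label=scen_label, period=period_label, gcm_label=gcm,
                    warming_offset=warm + dwarm, precip_factor=pfac * dp,
                    forest_to_crop_rate=0.0, seed=0,
                )
                gcm_stack = generate_future_stack(land_stack, clim_spec)
                gcm_maps.append(project_suitability(model, gcm_stack, chosen_radii))
            mean_suit = average_gcms(gcm_maps)
            mean_suit.to_ascii(out / f"suitability_{scen_label}_{period_label}.asc")
            fb = bin_suitability(mean_suit)
            fb.insert(0, "period", period_label)
            fb.insert(0, "scenario", scen_label)
            bin_tables.append(fb)
            fut_bin = binarize(mean_suit, model.threshold_maxsss, scen_label, period_label)
            for mode in ("perfect", "limited"):
                constrained = apply_dispersal_mask(
                    fut_bin, mode, range_polygon, config.dispersal_buffer_km
                )
                period_binaries[mode].append(constrained)
                change_rows[mode].append(change_metrics(current_bin, constrained).as_row())
        for mode in ("perfect", "limited"):
            ts = time_step_map(period_binaries[mode])
            if mode == "perfect":
                ts.grid.to_ascii(out / f"timestep_{scen_label}.asc")
            areas = ts.class_areas()
            areas.update(
                scenario=scen_label,
                dispersal=mode,
                resilient_km2=resilient_area(period_binaries[mode]),
            )
            timestep_rows.append(areas)
    _write_csv(pd.concat(bin_tables, ignore_index=True), out / "table2_analog_bins.csv")
    _write_csv(pd.DataFrame(change_rows["perfect"]), out / "table3_analog_perfect.csv")
    _write_csv(pd.DataFrame(change_rows["limited"]), out / "table3_analog_limited.csv")
    _write_csv(pd.DataFrame(timestep_rows), out / "timestep_class_areas.csv")
    tick("projection_change")

    # -- stage: range dynamics ---------------------------------------------
    if config.mode == "synthetic":
        warmed = generate_future_stack(
            stack,
            ScenarioSpec(label="shifted", period="b", warming_offset=1.0, seed=0),
        )
        suit_b = true_suitability(warmed, truth)
        occ_b = sample_occurrences(
            suit_b, len(occ), seed=config.seed + 6, elevation=stack["elevation"], year=2024
        )
        region_a = mcp(occ.coordinates())
        region_b = mcp(occ_b.coordinates())
        overlap = mcp_overlap(region_a, region_b)
        shift = elevation_shift(occ, occ_b, stack["elevation"])
        _write_csv(
            pd.DataFrame(
                [
                    {
                        "mcp_area_a_km2": region_a.area / 1e6,
                        "mcp_area_b_km2": region_b.area / 1e6,
                        "overlap_frac_a": overlap["frac_a"],
                        "overlap_frac_b": overlap["frac_b"],
                        "mean_elev_a": shift["mean_a"],
                        "mean_elev_b": shift["mean_b"],
                        "elev_delta": shift["delta"],
                    }
                ]
            ),
            out / "range_dynamics.csv",
        )
    tick("range_dynamics")

    # -- manifest -----------------------------------------------------------
    config.to_yaml(out / "config_used.yaml")
    for path in sorted(out.iterdir()):
        if path.name == "manifest.yaml" or path.is_dir():
            continue
        manifest.outputs[path.name] = _sha256(path)
    manifest.to_yaml(out / "manifest.yaml")
    return manifest
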