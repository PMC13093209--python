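"""Raster/CSV I/O, run configuration, and the end-to-end pipeline driver.

Rasters travel as ESRI ASCII grids (NCOLS/NROWS/XLLCORNER/YLLCORNER/
CELLSIZE/NODATA_VALUE header, row-major north-to-south values) — a plain
text dialect every GIS reads and writes. The driver executes the full
analysis in order: occurrence thinning, collinearity screening,
pseudo-absence sampling, fold construction, multi-algorithm fitting and
evaluation, TSS-based member selection, per-period committee averaging,
Jenks classification, area and change accounting, and the standard
deviational ellipse centroid track. Every numeric setting defaults to
the standard study configuration (|r| < 0.80 screen, 10,000
pseudo-absences, 4 folds, TSS > 0.70 selection, 4 suitability classes
with 2 for the historical period), and all randomness flows from the
config seed, so a fixed config reproduces its report byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ensemble as ens
from . import mapping as mp
from . import models as mdl
from . import range_dynamics as rd
from .grids import GridSpec
from .occurrences import OccurrenceSet, clean_occurrences, read_occurrences, thin_to_grid
from .predictors import CATEGORICAL, CONTINUOUS, EnvStack, Layer, extract_values, pearson_screen
from .synthetic import (
    LandscapeConfig,
    ScenarioDelta,
    apply_scenario_delta,
    generate_env_stack,
    make_virtual_species,
    sample_presences,
)

NODATA_DEFAULT = -9999.0


class PipelineError(RuntimeError):
    """A stage failure, labelled with the stage that raised it."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


# ---------------------------------------------------------------------------
# ESRI ASCII rasters


def read_raster(path) -> tuple[np.ndarray, GridSpec]:
    """Read an ESRI ASCII grid; nodata cells become NaN."""
    header: dict[str, float] = {}
    keys = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize"}
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in keys | {"nodata_value"}:
            try:
                header[parts[0].lower()] = float(parts[1])
            except ValueError as e:
                raise ValueError(f"malformed header line {i + 1}: {lines[i]!r}") from e
            i += 1
        else:
            break
    missing = keys - set(header)
    if missing:
        raise ValueError(f"incomplete ESRI ASCII header; missing {sorted(missing)}")
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    nodata = header.get("nodata_value", NODATA_DEFAULT)
    vals = np.loadtxt(lines[i:], dtype=float, ndmin=2)
    if vals.shape != (n_rows, n_cols):
        vals = vals.reshape(n_rows, n_cols)
    vals[vals == nodata] = np.nan
    cellsize_deg = header["cellsize"]
    grid = GridSpec(
        origin_lon=header["xllcorner"],
        origin_lat=header["yllcorner"] + n_rows * cellsize_deg,
        resolution=cellsize_deg * 60.0,
        n_rows=n_rows,
        n_cols=n_cols,
    )
    return vals, grid


def write_raster(values: np.ndarray, grid: GridSpec, path, nodata: float = NODATA_DEFAULT):
    """Write an ESRI ASCII grid; NaN cells become the nodata value.

    Values are written with full repr precision, so a read-back
    reproduces the array bit for bit.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != grid.shape:
        raise ValueError("values shape does not match grid")
    out = np.where(np.isfinite(values), values, nodata)
    with open(path, "w") as fh:
        fh.write(f"NCOLS {grid.n_cols}\n")
        fh.write(f"NROWS {grid.n_rows}\n")
        fh.write(f"XLLCORNER {grid.origin_lon!r}\n")
        fh.write(f"YLLCORNER {grid.origin_lat - grid.n_rows * grid.res_deg!r}\n")
        fh.write(f"CELLSIZE {grid.res_deg!r}\n")
        fh.write(f"NODATA_VALUE {nodata!r}\n")
        for row in out:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class PeriodSpec:
    """One projection period: a label, per-layer offsets, and a class count."""

    label: str
    offsets: dict[str, float] = field(default_factory=dict)
    k: int = 4  # 4-level; 2 for coarse historical reconstructions


@dataclass
class RunConfig:
    """Everything a pipeline run needs; defaults follow the standard setup."""

    landscape: LandscapeConfig | None = None
    species_terms: list[tuple[str, float, float, float]] = field(default_factory=list)
    prevalence: float = 0.10
    n_presences: int = 150
    occurrences_csv: str | None = None
    layer_files: list[tuple[str, str, str]] = field(default_factory=list)  # name, kind, path
    periods: list[PeriodSpec] = field(default_factory=lambda: [PeriodSpec("current")])
    baseline: str = "current"
    screen_threshold: float = 0.80
    retain: list[str] | None = None
    algorithms: list[str] = field(default_factory=lambda: list(mdl.ALGORITHMS))
    n_pseudo_absences: int = 10000
    folds: int = 4
    tss_min: float = 0.70
    sre_quantile: float = 2.5
    n_perm: int = 10
    n_response_curves: int = 2
    seed: int = 0
    output_dir: str | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.landscape is not None:
            d["landscape"]["target_correlation"] = (
                None
                if self.landscape.target_correlation is None
                else np.asarray(self.landscape.target_correlation).tolist()
            )
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """Build a RunConfig from a plain JSON file."""
    raw = json.loads(Path(path).read_text())
    if "landscape" in raw and raw["landscape"] is not None:
        ls = raw["landscape"]
        from .synthetic import LayerSpec

        ls["layer_specs"] = [LayerSpec(**s) for s in ls.get("layer_specs", [])]
        if ls.get("target_correlation") is not None:
            ls["target_correlation"] = np.asarray(ls["target_correlation"], dtype=float)
        raw["landscape"] = LandscapeConfig(**ls)
    raw["periods"] = [PeriodSpec(**p) for p in raw.get("periods", [{"label": "current"}])]
    raw["species_terms"] = [tuple(t) for t in raw.get("species_terms", [])]
    raw["layer_files"] = [tuple(t) for t in raw.get("layer_files", [])]
    return RunConfig(**raw)


@dataclass
class RunReport:
    """Everything a run computed, regenerable from its manifest."""

    screen: dict
    evaluation: pd.DataFrame
    selected: list[str]
    excluded: list[dict]
    ensemble_skill: dict
    importance: pd.DataFrame
    area_reports: dict[str, mp.AreaReport]
    change_reports: list[mp.ChangeReport]
    ellipses: list[rd.DeviationalEllipse]
    track: rd.CentroidTrack
    manifest: dict
    maps: dict[str, ens.SuitabilityMap] = field(default_factory=dict)
    classified: dict[str, mp.ClassifiedMap] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "manifest": self.manifest,
            "screen": self.screen,
            "evaluation": self.evaluation.round(9).to_dict(orient="records"),
            "selected": self.selected,
            "excluded": self.excluded,
            "ensemble_skill": {
                k: v for k, v in self.ensemble_skill.items() if k != "per_fold"
            },
            "importance": self.importance.round(9).reset_index().to_dict(orient="records"),
            "areas": {p: r.to_dict() for p, r in self.area_reports.items()},
            "changes": [c.to_dict() for c in self.change_reports],
            "ellipses": [e.to_dict() for e in self.ellipses],
            "track": self.track.to_rows(),
        }


# ---------------------------------------------------------------------------
# Driver


def _stage(name):
    def deco(fn):
        def wrapper(*a, **kw):
            try:
                return fn(*a, **kw)
            except PipelineError:
                raise
            except Exception as e:  # noqa: BLE001 - annotate and rethrow
                raise PipelineError(name, e) from e

        return wrapper

    return deco


def _load_stack(config: RunConfig) -> EnvStack:
    if config.landscape is not None:
        return generate_env_stack(config.landscape)
    if not config.layer_files:
        raise ValueError("config needs either a synthetic landscape or layer files")
    layers = {}
    grid = None
    mask = None
    for name, kind, path in config.layer_files:
        vals, g = read_raster(path)
        if grid is None:
            grid = g
            mask = np.isfinite(vals)
        elif g != grid:
            raise ValueError(f"layer {name!r} grid differs; align rasters first")
        else:
            mask &= np.isfinite(vals)
        layers[name] = Layer(kind, vals)
    for layer in layers.values():
        layer.values[~mask] = np.nan
    return EnvStack(grid, layers, mask)


def _get_occurrences(config: RunConfig, stack: EnvStack) -> OccurrenceSet:
    if config.occurrences_csv:
        occ = read_occurrences(config.occurrences_csv)
    else:
        if not config.species_terms:
            raise ValueError("synthetic runs need species_terms")
        species = make_virtual_species(stack, config.species_terms, config.prevalence)
        occ = sample_presences(species, stack, config.n_presences, seed=config.seed + 1)
    occ = clean_occurrences(occ)
    return thin_to_grid(occ, stack.grid)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full analysis; see the module docstring for the stages."""
    stack = _stage("landscape")(_load_stack)(config)
    occ = _stage("occurrences")(_get_occurrences)(config, stack)

    screen = _stage("screen")(pearson_screen)(
        stack, threshold=config.screen_threshold, seed=config.seed, retain=config.retain
    )
    model_layers = screen.retained + stack.categorical_names()
    model_stack = stack.subset(model_layers)

    pa = _stage("pseudo_absences")(mdl.sample_pseudo_absences)(
        model_stack, occ, n=config.n_pseudo_absences, seed=config.seed + 2
    )

    @_stage("training_table")
    def _tables():
        pres = extract_values(model_stack, occ)
        pres = pres[~pres["masked"]].drop(columns=["masked"])
        ab = extract_values(model_stack, pa)
        ab = ab[~ab["masked"]].drop(columns=["masked"])
        levels = {
            n: sorted(np.unique(model_stack.layers[n].values[model_stack.mask]).tolist())
            for n in model_stack.categorical_names()
        }
        return mdl.encode_predictors(pres, levels), mdl.encode_predictors(ab, levels), levels

    pres_enc, ab_enc, levels = _tables()
    data = _stage("folds")(mdl.make_folds)(
        pres_enc, ab_enc, k=config.folds, seed=config.seed + 3
    )

    evals = _stage("fit_evaluate")(mdl.evaluate_algorithms)(
        config.algorithms,
        data,
        continuous=screen.retained,
        sre_quantile=config.sre_quantile,
        seed=config.seed + 4,
        categorical_levels=levels,
    )
    eval_table = pd.DataFrame(
        [
            {
                "algorithm": e.algorithm,
                "fold": e.fold,
                "auc": e.auc,
                "tss": e.tss,
                "threshold": e.threshold,
                "sensitivity": e.sensitivity,
                "specificity": e.specificity,
            }
            for e in evals
        ]
    )

    committee = _stage("select_members")(ens.select_members)(evals, tss_min=config.tss_min)
    skill = _stage("evaluate_ensemble")(ens.evaluate_ensemble)(committee, data)

    raw_rows = pd.concat(
        [
            extract_values(model_stack, occ).query("~masked"),
            extract_values(model_stack, pa).query("~masked"),
        ],
        ignore_index=True,
    )[model_layers]
    importance = _stage("importance")(ens.variable_importance)(
        committee, raw_rows, variables=model_layers, n_perm=config.n_perm,
        seed=config.seed + 5,
    )

    curves = {}
    top_vars = [
        v for v in importance.table["mean"].sort_values(ascending=False).index
        if v in screen.retained
    ][: config.n_response_curves]
    for v in top_vars:
        curves[v] = _stage("response_curves")(ens.response_curve)(
            committee, model_stack, v
        )

    maps: dict[str, ens.SuitabilityMap] = {}
    classified: dict[str, mp.ClassifiedMap] = {}
    areas: dict[str, mp.AreaReport] = {}
    ellipses: list[rd.DeviationalEllipse] = []
    for period in config.periods:
        @_stage(f"period:{period.label}")
        def _one_period(period=period):
            pstack = (
                apply_scenario_delta(model_stack, ScenarioDelta(period.label, period.offsets))
                if period.offsets
                else model_stack
            )
            smap = ens.predict_ensemble_map(committee, pstack, period=period.label)
            cmap = mp.classify_map(smap, k=period.k, period=period.label, seed=config.seed)
            points, weights = rd.suitable_weights(cmap, smap)
            ell = rd.standard_deviational_ellipse(points, weights, period=period.label)
            return smap, cmap, mp.area_report(cmap), ell

        smap, cmap, rep, ell = _one_period()
        maps[period.label] = smap
        classified[period.label] = cmap
        areas[period.label] = rep
        ellipses.append(ell)

    changes = [
        _stage("change_reports")(mp.change_report)(
            classified[a.label], classified[b.label]
        )
        for a, b in zip(config.periods[:-1], config.periods[1:])
    ]
    if len(ellipses) >= 2:
        track = _stage("centroid_track")(rd.build_centroid_track)(ellipses)
    else:  # single-period run: a track with no displacements
        track = rd.CentroidTrack(
            periods=[ellipses[0].period],
            centroids=[(ellipses[0].center_lon, ellipses[0].center_lat)],
            displacements_km=[],
            bearings_deg=[],
            compass=[],
        )

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seeds": {
            "root": config.seed,
            "presences": config.seed + 1,
            "pseudo_absences": config.seed + 2,
            "folds": config.seed + 3,
            "fitting": config.seed + 4,
            "importance": config.seed + 5,
        },
        "n_occurrences": len(occ),
        "n_pseudo_absences": len(pa),
    }
    report = RunReport(
        screen=screen.to_dict(),
        evaluation=eval_table,
        selected=committee.selected,
        excluded=committee.excluded,
        ensemble_skill=skill,
        importance=importance.table,
        area_reports=areas,
        change_reports=changes,
        ellipses=ellipses,
        track=track,
        manifest=manifest,
        maps=maps,
        classified=classified,
    )
    if config.output_dir:
        _write_artifacts(report, curves, Path(config.output_dir))
    return report


def _write_artifacts(report: RunReport, curves: dict, out: Path):
    rasters = out / "rasters"
    tables = out / "tables"
    rasters.mkdir(parents=True, exist_ok=True)
    tables.mkdir(parents=True, exist_ok=True)
    for period, smap in report.maps.items():
        write_raster(smap.values, smap.grid, rasters / f"suitability_{period}.asc")
    for period, cmap in report.classified.items():
        write_raster(
            np.where(cmap.mask, cmap.classes.astype(float), np.nan),
            cmap.grid,
            rasters / f"classes_{period}.asc",
        )
        (rasters / f"classes_{period}.breaks.json").write_text(
            json.dumps({"labels": cmap.labels, "breaks": cmap.breaks}, indent=2)
        )
    report.evaluation.to_csv(tables / "evaluation.csv", index=False)
    report.importance.to_csv(tables / "importance.csv")
    for v, curve in curves.items():
        pd.DataFrame({"probe": curve.probes, "score": curve.scores}).to_csv(
            tables / f"response_{v}.csv", index=False
        )
    pd.DataFrame(report.track.to_rows()).to_csv(tables / "centroid_track.csv", index=False)
    pd.DataFrame([e.to_dict() for e in report.ellipses]).to_csv(
        tables / "ellipses.csv", index=False
    )
    (out / "report.json").write_text(
        json.dumps(report.to_dict(), indent=2, sort_keys=True, default=float)
    )
    (out / "manifest.json").write_text(
        json.dumps(report.manifest, indent=2, sort_keys=True, default=str)
    )
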