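"""Aligned environmental predictor stacks and the collinearity screen.

An :class:`EnvStack` holds named raster layers — continuous bioclimatic
surfaces and categorical land-cover style layers — on one shared
:class:`~sdmshift.grids.GridSpec` with a common study-area mask. Before
modelling, continuous layers are screened for pairwise redundancy:
layers are greedily eliminated until every retained pair has
|Pearson r| below a threshold (0.80 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .grids import GridSpec

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"


@dataclass
class Layer:
    kind: str  # continuous | categorical
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in (CONTINUOUS, CATEGORICAL):
            raise ValueError(f"unknown layer kind {self.kind!r}")
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class EnvStack:
    """Named raster layers on a shared grid with a boolean study-area mask."""

    grid: GridSpec
    layers: dict[str, Layer]
    mask: np.ndarray  # True = inside study area

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid")
        for name, layer in self.layers.items():
            if layer.values.shape != self.grid.shape:
                raise ValueError(f"layer {name!r} shape does not match grid")
            if layer.kind == CONTINUOUS and not np.all(
                np.isfinite(layer.values[self.mask])
            ):
                raise ValueError(f"layer {name!r} has non-finite values inside mask")

    @property
    def layer_names(self) -> list[str]:
        return list(self.layers)

    def continuous_names(self) -> list[str]:
        return [n for n, l in self.layers.items() if l.kind == CONTINUOUS]

    def categorical_names(self) -> list[str]:
        return [n for n, l in self.layers.items() if l.kind == CATEGORICAL]

    def subset(self, names: list[str]) -> "EnvStack":
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise KeyError(f"layers not in stack: {missing}")
        return EnvStack(self.grid, {n: self.layers[n] for n in names}, self.mask.copy())

    def copy(self) -> "EnvStack":
        return EnvStack(
            self.grid,
            {n: Layer(l.kind, l.values.copy()) for n, l in self.layers.items()},
            self.mask.copy(),
        )

    def table(self) -> pd.DataFrame:
        """All unmasked cells as a table (row, col, lon, lat, one column per layer)."""
        rows, cols = np.nonzero(self.mask)
        lon, lat = self.grid.cell_center(rows, cols)
        data = {"row": rows, "col": cols, "lon": lon, "lat": lat}
        for name, layer in self.layers.items():
            data[name] = layer.values[rows, cols]
        return pd.DataFrame(data)


@dataclass
class ScreenReport:
    """Outcome of the pairwise-correlation screen."""

    retained: list[str]
    dropped: list[dict] = field(default_factory=list)  # name, reason, partner, abs_r
    correlation: pd.DataFrame | None = None
    threshold: float = 0.80

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "retained": self.retained,
            "dropped": self.dropped,
            "correlation": None
            if self.correlation is None
            else self.correlation.round(6).to_dict(),
        }


def align_stack(
    layers: list[tuple[str, str, np.ndarray, GridSpec]],
    target: GridSpec,
    nodata: float = np.nan,
) -> EnvStack:
    """Resample rasters on heterogeneous grids onto a common target grid.

    Continuous layers are resampled bilinearly, categorical layers by
    nearest neighbour; target cells falling outside a source extent, or on
    a nodata source cell, are masked out of the resulting stack.

    Parameters
    ----------
    layers:
        Sequence of ``(name, kind, values, grid)`` tuples.
    target:
        The common output grid (2.5-arcmin in the standard pipeline).
    """
    out_layers: dict[str, Layer] = {}
    mask = np.ones(target.shape, dtype=bool)
    tlon = target.lon_centers()
    tlat = target.lat_centers()
    glon, glat = np.meshgrid(tlon, tlat)
    pts = np.column_stack([glat.ravel(), glon.ravel()])

    for name, kind, values, grid in layers:
        values = np.asarray(values, dtype=float)
        if values.shape != grid.shape:
            raise ValueError(f"layer {name!r}: values shape does not match its grid")
        src_lat = grid.lat_centers()  # strictly decreasing
        src_lon = grid.lon_centers()
        if (
            tlon.min() > src_lon.max() + grid.res_deg
            or tlon.max() < src_lon.min() - grid.res_deg
            or tlat.min() > src_lat.max() + grid.res_deg
            or tlat.max() < src_lat.min() - grid.res_deg
        ):
            raise ValueError(f"layer {name!r}: extent disjoint from target grid")
        method = "linear" if kind == CONTINUOUS else "nearest"
        vals = values.copy()
        if np.isfinite(nodata):
            vals[np.isclose(vals, nodata)] = np.nan
        bad = ~np.isfinite(vals)
        # interpolate a validity indicator with the same stencil, so a target
        # cell is masked iff its interpolation draws weight from a nodata cell
        valid = (~bad).astype(float)
        filled = np.where(bad, 0.0, vals)
        interp = RegularGridInterpolator(
            (src_lat[::-1], src_lon),
            filled[::-1, :],
            method=method,
            bounds_error=False,
            fill_value=np.nan,
        )
        vinterp = RegularGridInterpolator(
            (src_lat[::-1], src_lon),
            valid[::-1, :],
            method=method,
            bounds_error=False,
            fill_value=0.0,
        )
        res = interp(pts).reshape(target.shape)
        ok = vinterp(pts).reshape(target.shape) > 1.0 - 1e-9
        res[~ok] = np.nan
        mask &= ok & np.isfinite(res)
        out_layers[name] = Layer(kind, res)

    if not mask.any():
        raise ValueError("no cell is covered by every layer: extents disjoint")
    for layer in out_layers.values():
        layer.values[~mask] = np.nan
    return EnvStack(target, out_layers, mask)


def extract_values(stack: EnvStack, points) -> pd.DataFrame:
    """Look up layer values of the cells containing each point.

    ``points`` is anything exposing ``lon``/``lat`` columns (a DataFrame, an
    :class:`~sdmshift.occurrences.OccurrenceSet`) or an (n, 2) array of
    (lon, lat). Returns one row per point with a ``masked`` flag for points
    landing on masked or out-of-extent cells.
    """
    if hasattr(points, "frame"):
        pts = points.frame[["lon", "lat"]]
    elif isinstance(points, pd.DataFrame):
        pts = points[["lon", "lat"]]
    else:
        arr = np.asarray(points, dtype=float).reshape(-1, 2)
        pts = pd.DataFrame(arr, columns=["lon", "lat"])
    row, col = stack.grid.cell_index(pts["lon"].to_numpy(), pts["lat"].to_numpy())
    out = {"lon": pts["lon"].to_numpy(), "lat": pts["lat"].to_numpy()}
    inside = row >= 0
    masked = ~inside | ~stack.mask[np.clip(row, 0, None), np.clip(col, 0, None)]
    for name, layer in stack.layers.items():
        vals = np.full(len(pts), np.nan)
        vals[inside] = layer.values[row[inside], col[inside]]
        out[name] = vals
    out["masked"] = masked
    return pd.DataFrame(out)


def pearson_screen(
    stack: EnvStack,
    threshold: float = 0.80,
    sample_cells: int | None = None,
    seed: int = 0,
    retain: list[str] | None = None,
) -> ScreenReport:
    """Greedy collinearity screen over the stack's continuous layers.

    Pairwise Pearson correlations are computed across unmasked cells
    (optionally a seeded random sample of them for large grids). While any
    pair violates |r| >= threshold, the layer involved in the most
    violations is dropped; ties break by larger mean absolute correlation,
    then by reverse input order. Zero-variance layers are dropped up front.
    Categorical layers never enter the matrix and are always retained.

    ``retain`` forces the listed layers to be kept: their partners are
    dropped instead when a violating pair contains a forced layer.
    """
    cont = stack.continuous_names()
    if len(cont) < 2:
        raise ValueError("need at least two continuous layers to screen")
    m = stack.mask
    if int(m.sum()) < 30:
        raise ValueError("need at least 30 unmasked cells")
    data = np.column_stack([stack.layers[n].values[m] for n in cont])
    if sample_cells is not None and sample_cells < data.shape[0]:
        rng = np.random.default_rng(seed)
        idx = rng.choice(data.shape[0], size=sample_cells, replace=False)
        data = data[idx]

    retain = list(retain or [])
    dropped: list[dict] = []
    keep = list(cont)
    # zero-variance layers cannot be correlated against: remove first
    for name in list(keep):
        if np.std(data[:, cont.index(name)]) == 0:
            if name in retain:
                raise ValueError(f"forced layer {name!r} has zero variance")
            keep.remove(name)
            dropped.append(
                {"name": name, "reason": "zero variance", "partner": None, "abs_r": None}
            )

    corr_full = pd.DataFrame(
        np.corrcoef(data[:, [cont.index(n) for n in keep]], rowvar=False),
        index=keep,
        columns=keep,
    )

    def violations(names: list[str]) -> dict[str, list[str]]:
        viol: dict[str, list[str]] = {n: [] for n in names}
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                if abs(corr_full.loc[a, b]) >= threshold:
                    viol[a].append(b)
                    viol[b].append(a)
        return viol

    while True:
        viol = violations(keep)
        offenders = [n for n in keep if viol[n]]
        if not offenders:
            break
        candidates = [n for n in offenders if n not in retain]
        if not candidates:
            raise ValueError(
                "forced retain list itself violates the correlation threshold"
            )

        def sort_key(n: str):
            mean_abs = np.mean([abs(corr_full.loc[n, o]) for o in keep if o != n])
            return (len(viol[n]), mean_abs, cont.index(n))

        worst = max(candidates, key=sort_key)
        partner = max(viol[worst], key=lambda o: abs(corr_full.loc[worst, o]))
        dropped.append(
            {
                "name": worst,
                "reason": f"|r| >= {threshold} with {len(viol[worst])} layer(s)",
                "partner": partner,
                "abs_r": float(abs(corr_full.loc[worst, partner])),
            }
        )
        keep.remove(worst)

    sub = corr_full.loc[keep, keep]
    off = sub.to_numpy()[~np.eye(len(keep), dtype=bool)] if len(keep) > 1 else np.array([])
    if off.size and np.max(np.abs(off)) >= threshold:
        raise AssertionError("post-screen correlation violates threshold")
    return ScreenReport(
        retained=keep, dropped=dropped, correlation=corr_full, threshold=threshold
    )
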