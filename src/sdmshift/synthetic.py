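"""Synthetic landscapes, virtual species, and scenario deltas.

Every downstream stage of the pipeline — thinning, screening, model
fitting, ensembling, classification, centroid tracking — is validated
against inputs whose truth is known by construction. This module builds
them:

* spatially autocorrelated continuous layers with *exactly* controllable
  pairwise Pearson correlations (so the collinearity screen can be
  exercised above and below its 0.80 threshold), optional latitudinal
  trends (a temperature-like gradient), and categorical patch layers;
* a virtual species with Gaussian niche responses on named layers, its
  intercept calibrated so that mean true suitability hits a target
  prevalence;
* presence samples drawn from the true suitability surface, one record
  per cell;
* additive scenario offsets ("warming deltas") whose induced range
  displacement has a closed form — a layer trending at b units per degree
  latitude shifted by +dT moves any iso-suitability line poleward by dT/b
  degrees.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter
from scipy.special import expit

from .grids import GridSpec
from .occurrences import OccurrenceSet
from .predictors import CATEGORICAL, CONTINUOUS, EnvStack, Layer


@dataclass
class LayerSpec:
    name: str
    kind: str = CONTINUOUS
    trend_slope: float = 0.0  # units per degree latitude
    smoothing_length: int = 5  # moving-average window, cells
    std: float = 1.0  # noise amplitude around the trend, layer units
    n_classes: int = 4  # categorical layers only

    def __post_init__(self) -> None:
        if self.kind not in (CONTINUOUS, CATEGORICAL):
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.smoothing_length < 1:
            raise ValueError("smoothing_length must be >= 1 cell")


@dataclass
class LandscapeConfig:
    """Recipe for a synthetic environmental stack on a geographic grid."""

    n_rows: int
    n_cols: int
    origin_lon: float = 100.0
    origin_lat: float = 35.0
    resolution: float = 2.5  # arcminutes
    layer_specs: list[LayerSpec] = field(default_factory=list)
    target_correlation: np.ndarray | None = None  # over continuous layers, spec order
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 2 or self.n_cols < 2:
            raise ValueError("grid must be at least 2x2")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        n_cont = sum(1 for s in self.layer_specs if s.kind == CONTINUOUS)
        if self.target_correlation is not None:
            c = np.asarray(self.target_correlation, dtype=float)
            if c.shape != (n_cont, n_cont):
                raise ValueError(
                    f"target_correlation must be {n_cont}x{n_cont} for the "
                    f"{n_cont} continuous layers"
                )
            if not np.allclose(c, c.T):
                raise ValueError("target_correlation must be symmetric")
            if not np.allclose(np.diag(c), 1.0):
                raise ValueError("target_correlation must have unit diagonal")
            eig = np.linalg.eigvalsh(c)
            if eig.min() < -1e-8:
                raise ValueError(
                    "target_correlation is not positive semi-definite "
                    f"(min eigenvalue {eig.min():.3g})"
                )
            self.target_correlation = c

    @property
    def grid(self) -> GridSpec:
        return GridSpec(
            self.origin_lon, self.origin_lat, self.resolution, self.n_rows, self.n_cols
        )


@dataclass
class VirtualSpecies:
    """A species with known Gaussian niche responses.

    True suitability at a cell with layer values x is
    ``logistic(b0 + sum_v beta_v * exp(-(x_v - mu_v)^2 / (2 s_v^2)))``.
    """

    response_terms: list[tuple[str, float, float, float]]  # (layer, mu, s, beta)
    intercept: float
    prevalence_target: float

    def __post_init__(self) -> None:
        if not self.response_terms:
            raise ValueError("at least one response term required")
        for name, _mu, s, beta in self.response_terms:
            if s <= 0:
                raise ValueError(f"term {name!r}: breadth must be positive")
            if beta < 0:
                raise ValueError(f"term {name!r}: weight must be non-negative")

    def linear_predictor(self, stack: EnvStack) -> np.ndarray:
        eta = np.full(stack.grid.shape, self.intercept, dtype=float)
        for name, mu, s, beta in self.response_terms:
            x = stack.layers[name].values
            eta += beta * np.exp(-((x - mu) ** 2) / (2.0 * s * s))
        return eta

    def suitability(self, stack: EnvStack) -> np.ndarray:
        """True suitability grid in (0,1); NaN outside the mask."""
        p = expit(self.linear_predictor(stack))
        p = np.where(stack.mask, p, np.nan)
        return p


@dataclass
class ScenarioDelta:
    """Additive per-layer offsets describing a climate scenario."""

    label: str
    offsets: dict[str, float | np.ndarray] = field(default_factory=dict)


def _smooth_field(rng: np.random.Generator, shape, length: int) -> np.ndarray:
    noise = rng.standard_normal(shape)
    if length > 1:
        noise = uniform_filter(noise, size=length, mode="reflect")
    return noise


def generate_env_stack(config: LandscapeConfig) -> EnvStack:
    """Build the configured stack; deterministic for a fixed seed.

    Continuous layers: seeded white noise smoothed over ``smoothing_length``
    cells, the smoothed fields orthonormalized and mixed through a matrix
    square root of ``target_correlation`` — so the realized pairwise
    Pearson correlations over cells match the targets — then scaled to
    the layer's noise amplitude ``std`` and offset by the latitudinal
    trend. Trends add shared
    structure on top of the imposed correlation, so correlation targets
    are interpreted for the trend-free components.

    Categorical layers: contiguous patches from a nearest-seed (Voronoi)
    tessellation of random patch centres.
    """
    grid = config.grid
    rng = np.random.default_rng(config.seed)
    n_cells = config.n_rows * config.n_cols
    cont_specs = [s for s in config.layer_specs if s.kind == CONTINUOUS]

    fields = {}
    if cont_specs:
        z = np.column_stack(
            [
                _smooth_field(rng, grid.shape, s.smoothing_length).ravel()
                for s in cont_specs
            ]
        )
        z = z - z.mean(axis=0)
        # orthonormalize, then mix: empirical correlations equal the target exactly
        q, _ = np.linalg.qr(z)
        x = q * np.sqrt(n_cells)
        if config.target_correlation is not None and len(cont_specs) > 1:
            c = config.target_correlation
            w, v = np.linalg.eigh(c)
            root = v @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ v.T
            x = x @ root.T
        for i, spec in enumerate(cont_specs):
            fields[spec.name] = x[:, i].reshape(grid.shape)

    lat = grid.lat_centers()[:, None]
    lat_ref = lat.mean()
    layers: dict[str, Layer] = {}
    for spec in config.layer_specs:
        if spec.kind == CONTINUOUS:
            vals = spec.std * fields[spec.name] + spec.trend_slope * (lat - lat_ref)
            layers[spec.name] = Layer(CONTINUOUS, vals)
        else:
            n_seeds = max(3 * spec.n_classes, 6)
            sr = rng.uniform(0, config.n_rows, n_seeds)
            sc = rng.uniform(0, config.n_cols, n_seeds)
            lab = rng.integers(1, spec.n_classes + 1, n_seeds)
            rr, cc = np.meshgrid(
                np.arange(config.n_rows), np.arange(config.n_cols), indexing="ij"
            )
            d2 = (rr.ravel()[:, None] - sr) ** 2 + (cc.ravel()[:, None] - sc) ** 2
            vals = lab[np.argmin(d2, axis=1)].reshape(grid.shape).astype(float)
            layers[spec.name] = Layer(CATEGORICAL, vals)

    mask = np.ones(grid.shape, dtype=bool)
    return EnvStack(grid, layers, mask)


def make_virtual_species(
    stack: EnvStack,
    terms: list[tuple[str, float, float, float]],
    prevalence_target: float,
    max_iter: int = 60,
    tol: float = 0.005,
) -> VirtualSpecies:
    """Calibrate the niche intercept by bisection to a target prevalence.

    ``terms`` are (layer_name, optimum, breadth, weight) tuples on
    continuous layers. The intercept b0 is found so that the mean true
    suitability over unmasked cells is within ``tol`` of
    ``prevalence_target``.
    """
    for name, _mu, _s, _beta in terms:
        if name not in stack.layers:
            raise KeyError(f"layer {name!r} not in stack")
        if stack.layers[name].kind != CONTINUOUS:
            raise ValueError(f"layer {name!r} is categorical; niches need continuous layers")
    lo, hi = -60.0, 60.0

    def mean_suit(b0: float) -> float:
        sp = VirtualSpecies(terms, b0, prevalence_target)
        return float(np.nanmean(sp.suitability(stack)))

    p_lo, p_hi = mean_suit(lo), mean_suit(hi)
    if not (p_lo <= prevalence_target <= p_hi):
        raise ValueError(
            f"prevalence {prevalence_target} unattainable; achievable interval "
            f"approx [{p_lo:.4g}, {p_hi:.4g}]"
        )
    b0 = 0.0
    for _ in range(max_iter):
        b0 = 0.5 * (lo + hi)
        p = mean_suit(b0)
        if abs(p - prevalence_target) <= tol:
            break
        if p < prevalence_target:
            lo = b0
        else:
            hi = b0
    return VirtualSpecies(terms, b0, prevalence_target)


def sample_presences(
    species: VirtualSpecies, stack: EnvStack, n: int, seed: int = 0
) -> OccurrenceSet:
    """Draw n presence cells without replacement, P(cell) ∝ true suitability.

    Returned records sit at cell centers, mirroring the one-record-per-cell
    structure of thinned field data.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    p = species.suitability(stack)
    rows, cols = np.nonzero(stack.mask)
    weights = p[rows, cols]
    positive = weights > 0
    if n > int(positive.sum()):
        raise ValueError(
            f"requested {n} presences but only {int(positive.sum())} cells have "
            "positive suitability"
        )
    rng = np.random.default_rng(seed)
    idx = np.nonzero(positive)[0]
    w = weights[idx]
    chosen = rng.choice(idx, size=n, replace=False, p=w / w.sum(), shuffle=False)
    lon, lat = stack.grid.cell_center(rows[chosen], cols[chosen])
    frame = pd.DataFrame(
        {
            "id": [f"vs{i}" for i in range(n)],
            "lon": lon,
            "lat": lat,
            "source": "virtual-species",
            "grid_row": rows[chosen],
            "grid_col": cols[chosen],
        }
    )
    return OccurrenceSet(frame=frame, grid=stack.grid)


def apply_scenario_delta(stack: EnvStack, delta: ScenarioDelta) -> EnvStack:
    """Return a new stack with the scenario's additive offsets applied.

    Grid, mask, and categorical layers are untouched; the input stack is
    not modified.
    """
    out = stack.copy()
    for name, off in delta.offsets.items():
        if name not in stack.layers:
            raise KeyError(f"offset for unknown layer {name!r}")
        layer = stack.layers[name]
        if layer.kind != CONTINUOUS:
            raise ValueError(f"cannot offset categorical layer {name!r}")
        off_arr = np.asarray(off, dtype=float)
        if off_arr.ndim not in (0, 2):
            raise ValueError(f"offset for {name!r} must be scalar or a grid")
        if off_arr.ndim == 2 and off_arr.shape != stack.grid.shape:
            raise ValueError(f"offset grid for {name!r} does not match the stack grid")
        if not np.all(np.isfinite(off_arr)):
            raise ValueError(f"offset for {name!r} contains non-finite values")
        out.layers[name].values = out.layers[name].values + off_arr
    return out


def make_occurrence_table(
    grid: GridSpec,
    n_cells: int = 213,
    n_within_cell_extras: int = 40,
    n_exact_duplicates: int = 12,
    n_invalid: int = 3,
    include_zero: bool = True,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic stand-in for a compiled raw occurrence table.

    Emulates the messiness of a literature-compiled dataset: ``n_cells``
    distinct grid cells each hold one record (jittered off-center), some
    cells hold additional nearby records, some rows are exact coordinate
    duplicates, a few have impossible coordinates, and one sits at the
    (0, 0) sentinel. By construction, read -> clean -> thin on ``grid``
    recovers exactly ``n_cells`` records.
    """
    rng = np.random.default_rng(seed)
    n_grid_cells = grid.n_rows * grid.n_cols
    if n_cells > n_grid_cells:
        raise ValueError("more cells requested than the grid holds")
    flat = rng.choice(n_grid_cells, size=n_cells, replace=False)
    rows_, cols_ = np.divmod(flat, grid.n_cols)

    def jitter(row, col):
        # stay strictly inside the half-open cell
        u = rng.uniform(0.05, 0.95, size=np.shape(row))
        v = rng.uniform(0.05, 0.95, size=np.shape(row))
        lon = grid.origin_lon + (col + u) * grid.res_deg
        lat = grid.origin_lat - (row + v) * grid.res_deg
        return lon, lat

    lon, lat = jitter(rows_, cols_)
    recs = [
        {"id": f"occ{i}", "lon": lon[i], "lat": lat[i], "source": "literature"}
        for i in range(n_cells)
    ]
    # extra records inside already-occupied cells (removed by thinning)
    pick = rng.integers(0, n_cells, n_within_cell_extras)
    elon, elat = jitter(rows_[pick], cols_[pick])
    recs += [
        {"id": f"extra{i}", "lon": elon[i], "lat": elat[i], "source": "survey"}
        for i in range(n_within_cell_extras)
    ]
    # exact duplicates (removed by cleaning)
    for i, j in enumerate(rng.integers(0, len(recs), n_exact_duplicates)):
        recs.append({**recs[j], "id": f"dup{i}", "source": "duplicate-entry"})
    # malformed coordinates (rejected on read)
    for i in range(n_invalid):
        recs.append(
            {"id": f"bad{i}", "lon": 200.0 + i, "lat": 95.0 + i, "source": "typo"}
        )
    if include_zero:
        recs.append({"id": "zero", "lon": 0.0, "lat": 0.0, "source": "sentinel"})
    frame = pd.DataFrame(recs)
    return frame.sample(frac=1.0, random_state=int(rng.integers(0, 2**31))).reset_index(
        drop=True
    )
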