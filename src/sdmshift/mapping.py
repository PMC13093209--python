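"""Jenks natural-breaks classification, spherical areas, change accounting.

Committee-average suitability maps are classified per period into four
levels (unsuitable / low / moderate / high) — or two (unsuitable /
suitable) for coarse historical reconstructions — with break values
computed independently on each period's own score distribution. Class
areas use exact spherical cell areas on the R = 6371 km sphere and are
reported both in km^2 and in the 10^4 km^2 units conventional for
country-scale habitat totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ensemble import SuitabilityMap
from .grids import GridSpec

FOUR_LEVEL = ["unsuitable", "low", "moderate", "high"]
TWO_LEVEL = ["unsuitable", "suitable"]

_MAX_DISTINCT = 10_000  # above this, Jenks runs on a seeded value sample


def _segment_cost(W, WV, WV2, i, j):
    """Weighted SSD of sorted distinct values i..j (inclusive, prefix arrays)."""
    w = W[j + 1] - W[i]
    sv = WV[j + 1] - WV[i]
    sv2 = WV2[j + 1] - WV2[i]
    return sv2 - sv * sv / w


def jenks_breaks(values, k: int, seed: int = 0) -> list[float]:
    """Fisher-Jenks optimal 1-D classification into k classes.

    Minimizes the total within-class sum of squared deviations from class
    means by dynamic programming over the sorted distinct values (weighted
    by their multiplicities — exact, and fast on lattice-valued committee
    scores). Returns the k-1 break values, each the largest value of its
    lower class; cost ties resolve toward the smallest upper-class size.
    Inputs with more than 10^4 distinct values are subsampled (seeded)
    before the DP.
    """
    vals = np.asarray(values, dtype=float).ravel()
    vals = vals[np.isfinite(vals)]
    if k < 2:
        raise ValueError("k must be >= 2")
    uniq, counts = np.unique(vals, return_counts=True)
    if uniq.size < k:
        raise ValueError(f"need at least {k} distinct values, got {uniq.size}")
    if uniq.size > _MAX_DISTINCT:
        rng = np.random.default_rng(seed)
        sub = rng.choice(vals, size=_MAX_DISTINCT, replace=False)
        uniq, counts = np.unique(sub, return_counts=True)
    m = uniq.size
    W = np.concatenate([[0.0], np.cumsum(counts)])
    WV = np.concatenate([[0.0], np.cumsum(counts * uniq)])
    WV2 = np.concatenate([[0.0], np.cumsum(counts * uniq * uniq)])

    # D[c, j]: minimal cost of splitting values 0..j into c+1 classes
    idx = np.arange(m)
    D = _segment_cost(W, WV, WV2, 0, idx)  # one class
    split = np.zeros((k, m), dtype=int)
    for c in range(1, k):
        D_new = np.full(m, np.inf)
        for j in range(c, m):
            starts = np.arange(c, j + 1)  # class c starts at i, ends at j
            total = D[starts - 1] + _segment_cost(W, WV, WV2, starts, j)
            best = total.min()
            i_best = starts[np.nonzero(total == best)[0][-1]]  # latest split
            D_new[j] = best
            split[c, j] = i_best
        D = D_new

    # reconstruct: class k-1 is split[k-1, m-1] .. m-1, recurse on the rest
    breaks: list[float] = []
    j = m - 1
    for c in range(k - 1, 0, -1):
        i = split[c, j]
        breaks.append(float(uniq[i - 1]))
        j = i - 1
    return breaks[::-1]


@dataclass
class ClassifiedMap:
    """Integer habitat classes on a masked grid, with the breaks that made them."""

    grid: GridSpec
    classes: np.ndarray  # int class per cell; -1 outside mask
    mask: np.ndarray
    labels: list[str]  # ascending suitability order
    breaks: list[float]
    period: str = ""

    def __post_init__(self) -> None:
        if list(self.breaks) != sorted(self.breaks):
            raise ValueError("breaks must be increasing")
        if len(self.labels) != len(self.breaks) + 1:
            raise ValueError("need one more label than breaks")

    def is_suitable(self) -> np.ndarray:
        """Boolean grid: any non-'unsuitable' class."""
        return self.mask & (self.classes > 0)


def classify_map(
    suit: SuitabilityMap, k: int = 4, period: str = "", seed: int = 0
) -> ClassifiedMap:
    """Classify one period's suitability scores by its own Jenks breaks.

    ``k=4`` labels the classes unsuitable/low/moderate/high in ascending
    score order; ``k=2`` labels them unsuitable/suitable. Breaks are never
    reused across periods.
    """
    if k not in (2, 4):
        raise ValueError("k must be 2 or 4")
    vals = suit.masked_values()
    if np.unique(vals).size < 2:
        raise ValueError("constant suitability map: no breaks exist")
    breaks = jenks_breaks(vals, k, seed=seed)
    classes = np.full(suit.grid.shape, -1, dtype=int)
    classes[suit.mask] = np.searchsorted(breaks, vals, side="left")
    labels = FOUR_LEVEL if k == 4 else TWO_LEVEL
    return ClassifiedMap(
        grid=suit.grid,
        classes=classes,
        mask=suit.mask.copy(),
        labels=list(labels),
        breaks=breaks,
        period=period,
    )


def cell_areas(grid: GridSpec) -> np.ndarray:
    """Per-row spherical cell area in km^2 (see GridSpec.cell_areas_km2)."""
    return grid.cell_areas_km2()


def suitable_subtotal(per_class: dict[str, float]) -> float:
    """Sum a per-class quantity over all non-'unsuitable' classes."""
    return float(sum(v for lab, v in per_class.items() if lab != "unsuitable"))


@dataclass
class AreaReport:
    """Class areas and shares of the study area for one period."""

    period: str
    area_km2: dict[str, float]  # per class label
    percent: dict[str, float]  # per class, of study-area total
    total_km2: float

    @property
    def area_1e4km2(self) -> dict[str, float]:
        return {lab: a / 1e4 for lab, a in self.area_km2.items()}

    @property
    def suitable_km2(self) -> float:
        return suitable_subtotal(self.area_km2)

    @property
    def suitable_percent(self) -> float:
        return suitable_subtotal(self.percent)

    def to_dict(self) -> dict:
        return {
            "period": self.period,
            "total_1e4_km2": self.total_km2 / 1e4,
            "classes": {
                lab: {"area_1e4_km2": self.area_km2[lab] / 1e4, "percent": self.percent[lab]}
                for lab in self.area_km2
            },
            "suitable_1e4_km2": self.suitable_km2 / 1e4,
            "suitable_percent": self.suitable_percent,
        }


def area_report(classified: ClassifiedMap) -> AreaReport:
    """Exact spherical area and percentage per class; totals conserved."""
    row_areas = classified.grid.cell_areas_km2()
    area_grid = np.broadcast_to(row_areas[:, None], classified.grid.shape)
    total = float(area_grid[classified.mask].sum())
    areas: dict[str, float] = {}
    for ci, lab in enumerate(classified.labels):
        sel = classified.mask & (classified.classes == ci)
        areas[lab] = float(area_grid[sel].sum())
    percent = {lab: 100.0 * a / total for lab, a in areas.items()}
    return AreaReport(
        period=classified.period, area_km2=areas, percent=percent, total_km2=total
    )


@dataclass
class ChangeReport:
    """Suitable/unsuitable transition areas between two periods."""

    period_a: str
    period_b: str
    gain_km2: float
    loss_km2: float
    stable_suitable_km2: float
    stable_unsuitable_km2: float
    net_change_pct_points: float  # of study-area total
    net_change_pct_of_prior: float  # of period a's suitable area
    total_km2: float

    def to_dict(self) -> dict:
        return {
            "from": self.period_a,
            "to": self.period_b,
            "gain_1e4_km2": self.gain_km2 / 1e4,
            "loss_1e4_km2": self.loss_km2 / 1e4,
            "stable_suitable_1e4_km2": self.stable_suitable_km2 / 1e4,
            "stable_unsuitable_1e4_km2": self.stable_unsuitable_km2 / 1e4,
            "net_change_pct_points": self.net_change_pct_points,
            "net_change_pct_of_prior": self.net_change_pct_of_prior,
        }


def change_report(a: ClassifiedMap, b: ClassifiedMap) -> ChangeReport:
    """Area-weighted cross-tabulation of suitable/unsuitable transitions.

    Net change is reported in percentage points of the study area (and,
    separately labelled, as percent of the earlier period's suitable
    area).
    """
    if a.grid != b.grid or not np.array_equal(a.mask, b.mask):
        raise ValueError("periods must share grid and mask")
    row_areas = a.grid.cell_areas_km2()
    area_grid = np.broadcast_to(row_areas[:, None], a.grid.shape)
    sa, sb = a.is_suitable(), b.is_suitable()
    total = float(area_grid[a.mask].sum())
    gain = float(area_grid[~sa & sb & a.mask].sum())
    loss = float(area_grid[sa & ~sb & a.mask].sum())
    stable_s = float(area_grid[sa & sb].sum())
    stable_u = float(area_grid[~sa & ~sb & a.mask].sum())
    suit_a = float(area_grid[sa].sum())
    suit_b = float(area_grid[sb].sum())
    return ChangeReport(
        period_a=a.period,
        period_b=b.period,
        gain_km2=gain,
        loss_km2=loss,
        stable_suitable_km2=stable_s,
        stable_unsuitable_km2=stable_u,
        net_change_pct_points=100.0 * (suit_b - suit_a) / total,
        net_change_pct_of_prior=(100.0 * (suit_b - suit_a) / suit_a if suit_a else float("nan")),
        total_km2=total,
    )
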