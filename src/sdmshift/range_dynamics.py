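"""Standard deviational ellipses, centroids, and between-period migration.

The standard deviational ellipse (SDE) summarizes the weighted dispersion
and orientation of a period's suitable range: its center is the weighted
mean of the suitable cell centers (the distribution centroid), its axes
the weighted standard deviations along and across the dominant
orientation, rotated clockwise from north. Axis lengths carry the sqrt(2)
correction used by the one-standard-deviation ellipse of desktop GIS
tools, so ~63% of a bivariate normal cloud falls inside; a flag restores
the uncorrected textbook (Yuill) convention.

Ellipse geometry is computed in a local equirectangular plane about the
weighted mean (adequate at the 10^2 km scale of range ellipses);
between-centroid displacement uses the exact haversine great circle on
the R = 6371 km sphere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ensemble import SuitabilityMap
from .grids import EARTH_RADIUS_KM, KM_PER_DEGREE
from .mapping import ClassifiedMap

COMPASS = ["N", "NE", "E", "SE", "S", "SW", "W", "NW"]


@dataclass
class DeviationalEllipse:
    center_lon: float
    center_lat: float
    sigma_major_km: float
    sigma_minor_km: float
    rotation_deg: float  # clockwise from north, [0, 180)
    weight_total: float
    period: str = ""

    def to_dict(self) -> dict:
        return {
            "period": self.period,
            "center_lon": self.center_lon,
            "center_lat": self.center_lat,
            "sigma_major_km": self.sigma_major_km,
            "sigma_minor_km": self.sigma_minor_km,
            "rotation_deg": self.rotation_deg,
            "weight_total": self.weight_total,
        }


@dataclass
class CentroidTrack:
    periods: list[str]
    centroids: list[tuple[float, float]]  # (lon, lat)
    displacements_km: list[float]
    bearings_deg: list[float]  # NaN where undefined
    compass: list[str]

    def to_rows(self) -> list[dict]:
        rows = []
        for i, p in enumerate(self.periods):
            row = {"period": p, "lon": self.centroids[i][0], "lat": self.centroids[i][1]}
            if i > 0:
                row.update(
                    displacement_km=self.displacements_km[i - 1],
                    bearing_deg=self.bearings_deg[i - 1],
                    compass=self.compass[i - 1],
                )
            rows.append(row)
        return rows


def _sde_planar(x, y, w, axis_scale: float = np.sqrt(2.0)):
    """Core SDE geometry in a planar frame (x east, y north).

    Returns (theta_deg clockwise from north in [0, 180), sigma_major,
    sigma_minor) for deviations already centered on the weighted mean.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    sw = w.sum()
    A = np.sum(w * x * x) - np.sum(w * y * y)
    B = np.sum(w * x * y)
    if B == 0.0:
        theta = 0.0 if A >= 0 else np.pi / 2
    else:
        theta = np.arctan((A + np.hypot(A, 2.0 * B)) / (2.0 * B))
        if theta < 0:
            theta += np.pi
    ct, st = np.cos(theta), np.sin(theta)
    # sigma along the bearing-theta axis and its perpendicular
    s_along = axis_scale * np.sqrt(np.sum(w * (x * st + y * ct) ** 2) / sw)
    s_across = axis_scale * np.sqrt(np.sum(w * (x * ct - y * st) ** 2) / sw)
    if s_across > s_along:
        s_along, s_across = s_across, s_along
        theta = theta + np.pi / 2
    theta_deg = np.degrees(theta) % 180.0
    return float(theta_deg), float(s_along), float(s_across)


def standard_deviational_ellipse(
    points,
    weights=None,
    period: str = "",
    arcgis_scaling: bool = True,
) -> DeviationalEllipse:
    """Weighted SDE of (lon, lat) points.

    Points are projected to a local plane about the weighted mean
    (x = dlon * 111.195 * cos(mean lat) km, y = dlat * 111.195 km) and the
    orientation solved from the weighted deviations; axes are the rotated
    weighted standard deviations, times sqrt(2) unless
    ``arcgis_scaling=False``.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 points")
    w = np.ones(pts.shape[0]) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive total")
    sw = w.sum()
    lon0 = float(np.sum(w * pts[:, 0]) / sw)
    lat0 = float(np.sum(w * pts[:, 1]) / sw)
    x = (pts[:, 0] - lon0) * KM_PER_DEGREE * np.cos(np.radians(lat0))
    y = (pts[:, 1] - lat0) * KM_PER_DEGREE
    scale = np.sqrt(2.0) if arcgis_scaling else 1.0
    theta_deg, s_major, s_minor = _sde_planar(x, y, w, axis_scale=scale)
    return DeviationalEllipse(
        center_lon=lon0,
        center_lat=lat0,
        sigma_major_km=s_major,
        sigma_minor_km=s_minor,
        rotation_deg=theta_deg,
        weight_total=float(sw),
        period=period,
    )


def suitable_weights(classified: ClassifiedMap, scores: SuitabilityMap):
    """Suitable-cell centers with their ensemble scores as weights."""
    if classified.grid != scores.grid or not np.array_equal(classified.mask, scores.mask):
        raise ValueError("classified map and score map must share grid and mask")
    sel = classified.is_suitable()
    rows, cols = np.nonzero(sel)
    if rows.size == 0:
        raise ValueError("no suitable cells")
    lon, lat = classified.grid.cell_center(rows, cols)
    return np.column_stack([lon, lat]), scores.values[rows, cols]


def centroid_displacement(c1, c2) -> tuple[float, float]:
    """Great-circle distance (km, haversine, R = 6371) and initial bearing.

    Bearing is degrees clockwise from north in [0, 360); NaN when the
    points coincide.
    """
    lon1, lat1 = np.radians(np.asarray(c1, dtype=float))
    lon2, lat2 = np.radians(np.asarray(c2, dtype=float))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    dist = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))
    if dist == 0:
        return 0.0, float("nan")
    yb = np.sin(dlon) * np.cos(lat2)
    xb = np.cos(lat1) * np.sin(lat2) - np.sin(lat1) * np.cos(lat2) * np.cos(dlon)
    bearing = (np.degrees(np.arctan2(yb, xb)) + 360.0) % 360.0
    return float(dist), float(bearing)


def compass_label(bearing_deg: float) -> str:
    """45-degree sector compass label; 'none' for an undefined bearing."""
    if not np.isfinite(bearing_deg):
        return "none"
    return COMPASS[int(((bearing_deg + 22.5) % 360.0) // 45.0)]


def build_centroid_track(ellipses: list[DeviationalEllipse]) -> CentroidTrack:
    """Consecutive centroid displacement, bearing, and compass direction."""
    if len(ellipses) < 2:
        raise ValueError("need at least two periods")
    centroids = [(e.center_lon, e.center_lat) for e in ellipses]
    disps, bears, labels = [], [], []
    for a, b in zip(centroids[:-1], centroids[1:]):
        d, brg = centroid_displacement(a, b)
        disps.append(d)
        bears.append(brg)
        labels.append(compass_label(brg))
    return CentroidTrack(
        periods=[e.period for e in ellipses],
        centroids=centroids,
        displacements_km=disps,
        bearings_deg=bears,
        compass=labels,
    )
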