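"""From a 2D locality map to a signed 1D transect.

The hybrid-index surface is interpolated smoothly (C1 Clough-Tocher on a
Delaunay triangulation, the scattered-data analogue of the Akima splines
traditionally used for hybrid-zone isolines; piecewise-linear available as
an option), the 0.5 contour (the theoretical hybrid zone centre) is
extracted by marching squares, and each locality gets a signed great-circle
distance to that isoline: negative on the nesterovi side (hybrid index
below the level), positive on the ophryticus side. A smooth surface
matters here: with near-collinear locality chains, a piecewise-linear
surface threads its level set through triangulation slivers and pinches
the transect near the zone centre.

All geometry is spherical (WGS84 degrees in, kilometres out, Earth radius
6371.0 km); no projected CRS is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import (
    CloughTocher2DInterpolator,
    LinearNDInterpolator,
    NearestNDInterpolator,
)
from scipy.spatial import QhullError
from skimage import measure

from .data_model_io import LocalityFrame

EARTH_RADIUS_KM = 6371.0


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in km between two WGS84 points."""
    la1, lo1, la2, lo2 = np.radians([lat1, lon1, lat2, lon2])
    a = np.sin((la2 - la1) / 2) ** 2 + np.cos(la1) * np.cos(la2) * np.sin((lo2 - lo1) / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


def _haversine_vec(lat: np.ndarray, lon: np.ndarray, lat0: float, lon0: float) -> np.ndarray:
    la, lo = np.radians(lat), np.radians(lon)
    la0, lo0 = np.radians(lat0), np.radians(lon0)
    a = np.sin((la - la0) / 2) ** 2 + np.cos(la0) * np.cos(la) * np.sin((lo - lo0) / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


@dataclass
class HiSurface:
    """Hybrid-index values on a regular lat/lon grid (NaN outside the
    convex hull of the input localities)."""

    lat: np.ndarray     # ascending
    lon: np.ndarray     # ascending
    values: np.ndarray  # (n_lat, n_lon)
    _interp: CloughTocher2DInterpolator | LinearNDInterpolator
    _nearest: NearestNDInterpolator

    def at(self, lat: float, lon: float) -> float:
        """Interpolated hybrid index, falling back to nearest-node value
        outside the hull."""
        v = float(self._interp(lon, lat))
        if np.isnan(v):
            v = float(self._nearest(lon, lat))
        return v


@dataclass
class IsolineTransect:
    isoline: np.ndarray             # (n_vertices, 2) as (lat, lon)
    codes: list[str]
    distances_km: np.ndarray        # signed; negative = nesterovi side

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.codes, map(float, self.distances_km)))


def interpolate_hi_surface(
    localities: LocalityFrame, resolution: float = 0.01, method: str = "smooth"
) -> HiSurface:
    """Interpolate locality hybrid indices onto a regular grid over the
    locality bounding box.

    ``method='smooth'`` (default) uses the C1 Clough-Tocher interpolant;
    ``'linear'`` uses piecewise-linear triangulation. Both reproduce the
    node values exactly. ``resolution`` is the grid spacing in degrees.
    Raises for fewer than 3 localities or an all-collinear configuration
    (no triangulation exists).
    """
    f = localities.frame
    pts = np.column_stack([f["longitude"].to_numpy(float), f["latitude"].to_numpy(float)])
    vals = f["hybrid_index"].to_numpy(float)
    if len(pts) < 3:
        raise ValueError("need at least 3 localities to interpolate")
    cls = CloughTocher2DInterpolator if method == "smooth" else LinearNDInterpolator
    try:
        interp = cls(pts, vals)
    except QhullError as exc:
        raise ValueError("localities are collinear; no 2D interpolation possible") from exc
    if interp.tri.simplices.size == 0:  # pragma: no cover - qhull already errors
        raise ValueError("localities are collinear; no 2D interpolation possible")
    nearest = NearestNDInterpolator(pts, vals)
    lon = np.arange(pts[:, 0].min(), pts[:, 0].max() + resolution / 2, resolution)
    lat = np.arange(pts[:, 1].min(), pts[:, 1].max() + resolution / 2, resolution)
    gl, gt = np.meshgrid(lon, lat)
    values = interp(gl, gt)
    return HiSurface(lat, lon, values, interp, nearest)


def extract_isoline(
    surface: HiSurface, level: float = 0.5, clip_polygon: np.ndarray | None = None
) -> np.ndarray:
    """Marching-squares contour of the surface at ``level``.

    The hull-masked cells are filled with nearest-node values before
    contouring (marching squares needs a full grid); vertices falling
    outside the convex hull of the localities are then discarded (the
    isoline is not extrapolated beyond data coverage), contours are split
    at the resulting gaps, and the longest connected component is returned
    as an (n, 2) array of (lat, lon) vertices. ``clip_polygon`` (optional
    (m, 2) array of (lat, lon) vertices, e.g. a species-range outline)
    additionally drops vertices outside that polygon.
    """
    vals = surface.values.copy()
    nan = np.isnan(vals)
    if nan.any():
        gl, gt = np.meshgrid(surface.lon, surface.lat)
        vals[nan] = surface._nearest(gl[nan], gt[nan])
    finite = vals[np.isfinite(vals)]
    if finite.min() >= level or finite.max() <= level:
        raise ValueError("no contact in sampled area: surface never crosses level")
    contours = measure.find_contours(vals, level)
    if not contours:
        raise ValueError("no contact in sampled area: surface never crosses level")

    poly = None
    if clip_polygon is not None:
        from shapely.geometry import Point, Polygon

        poly = Polygon([(lon, lat) for lat, lon in clip_polygon])

    pieces: list[np.ndarray] = []
    for c in contours:
        lat = np.interp(c[:, 0], np.arange(surface.lat.size), surface.lat)
        lon = np.interp(c[:, 1], np.arange(surface.lon.size), surface.lon)
        keep = np.isfinite(surface._interp(lon, lat))  # inside the data hull
        if poly is not None:
            keep &= np.array([poly.contains(Point(lo, la)) for la, lo in zip(lat, lon)])
        if not keep.any():
            continue
        idx = np.flatnonzero(keep)
        breaks = np.flatnonzero(np.diff(idx) > 1)
        for seg in np.split(idx, breaks + 1):  # split at gaps, never re-join
            if seg.size >= 2:
                pieces.append(np.column_stack([lat[seg], lon[seg]]))
    if not pieces:
        raise ValueError("no contact within the sampled (clipped) area")

    def length(piece: np.ndarray) -> float:
        return float(np.sum(np.hypot(np.diff(piece[:, 0]), np.diff(piece[:, 1]))))

    return max(pieces, key=length)


def _densify(isoline: np.ndarray, max_step_km: float = 0.1) -> np.ndarray:
    """Insert vertices so consecutive points are <= max_step_km apart.

    Linear interpolation in lat/lon between vertices is adequate at the
    sub-km segment lengths produced by the contour grid.
    """
    pts = [isoline[0]]
    for a, b in zip(isoline[:-1], isoline[1:]):
        d = haversine_km(a[0], a[1], b[0], b[1])
        n = max(int(np.ceil(d / max_step_km)), 1)
        for t in np.linspace(0, 1, n + 1)[1:]:
            pts.append(a + t * (b - a))
    return np.asarray(pts)


def signed_distances(
    localities: LocalityFrame,
    isoline: np.ndarray,
    surface: HiSurface | None = None,
    level: float = 0.5,
    max_step_km: float = 0.1,
) -> IsolineTransect:
    """Signed great-circle distance of each locality to the isoline.

    The magnitude is the minimum distance to the isoline densified to
    ``max_step_km`` steps; the sign comes from the interpolated hybrid index
    at the locality (below ``level`` -> negative, the nesterovi side). When
    no surface is given the locality's own hybrid index decides the sign
    (identical at data points, since linear interpolation reproduces nodes).
    """
    if isoline.size == 0:
        raise ValueError("empty isoline")
    dense = _densify(isoline, max_step_km)
    f = localities.frame
    dists = np.empty(len(f))
    for i, row in enumerate(f.itertuples()):
        d = _haversine_vec(dense[:, 0], dense[:, 1], row.latitude, row.longitude)
        hi = (
            surface.at(row.latitude, row.longitude)
            if surface is not None
            else row.hybrid_index
        )
        sign = -1.0 if hi < level else (1.0 if hi > level else 0.0)
        dists[i] = sign * float(d.min())
    return IsolineTransect(isoline, list(f["code"].astype(str)), dists)


def build_transect(
    localities: LocalityFrame,
    resolution: float = 0.01,
    level: float = 0.5,
    method: str = "smooth",
) -> IsolineTransect:
    """Convenience chain: interpolate surface, extract isoline, sign distances."""
    surface = interpolate_hi_surface(localities, resolution, method)
    isoline = extract_isoline(surface, level)
    return signed_distances(localities, isoline, surface, level)
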