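"""Planar projection for walk-scale geographic data.

A local equirectangular projection centred on the data centroid maps
lat/lon degrees to metres.  At the sub-kilometre extents of a guided city
walk the distortion versus a conformal projection is well below GPS noise,
so nothing heavier is warranted.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_M = 6_371_008.8  # mean Earth radius


def to_planar(
    lat: np.ndarray,
    lon: np.ndarray,
    lat0: float | None = None,
    lon0: float | None = None,
) -> tuple[np.ndarray, np.ndarray, tuple[float, float]]:
    """Project lat/lon (degrees) to local planar metres.

    Returns ``(x, y, (lat0, lon0))`` where the origin defaults to the
    centroid of the input points; pass it back in to project further points
    into the same frame.
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if lat0 is None:
        lat0 = float(np.mean(lat))
    if lon0 is None:
        lon0 = float(np.mean(lon))
    k = np.pi / 180.0 * EARTH_RADIUS_M
    x = (lon - lon0) * k * np.cos(np.deg2rad(lat0))
    y = (lat - lat0) * k
    return x, y, (lat0, lon0)


def metres_to_degrees(dx_m: float, dy_m: float, lat0: float) -> tuple[float, float]:
    """Inverse scale factors: planar metre offsets to (dlat, dlon) degrees."""
    k = np.pi / 180.0 * EARTH_RADIUS_M
    return dy_m / k, dx_m / (k * np.cos(np.deg2rad(lat0)))
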