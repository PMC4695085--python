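"""Spatial autocorrelation of community composition.

GPS coordinates (WGS84 decimal degrees) are projected to planar meters
— by default with a transverse Mercator (UTM) projection computed from
the standard series expansions, or with a local equirectangular
projection about the points' centroid — and pairwise Euclidean
geographic distances are compared to community dissimilarities with a
Mantel permutation test.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

logger = logging.getLogger(__name__)

# WGS84 ellipsoid
_A = 6378137.0
_F = 1 / 298.257223563
_E2 = _F * (2 - _F)
_EP2 = _E2 / (1 - _E2)
_K0 = 0.9996
_FALSE_EASTING = 500_000.0
_FALSE_NORTHING_S = 10_000_000.0
_MEAN_RADIUS = 6_371_008.8


def utm_zone(longitude: float) -> int:
    return int((longitude + 180.0) // 6.0) + 1


def _meridian_arc(phi: float) -> float:
    e2, e4, e6 = _E2, _E2 ** 2, _E2 ** 3
    return _A * (
        (1 - e2 / 4 - 3 * e4 / 64 - 5 * e6 / 256) * phi
        - (3 * e2 / 8 + 3 * e4 / 32 + 45 * e6 / 1024) * math.sin(2 * phi)
        + (15 * e4 / 256 + 45 * e6 / 1024) * math.sin(4 * phi)
        - (35 * e6 / 3072) * math.sin(6 * phi)
    )


def latlon_to_utm(latitude: float, longitude: float,
                  zone: int | None = None) -> tuple[float, float, int]:
    """Forward transverse Mercator (UTM) projection; returns easting,
    northing (meters) and the zone used."""
    if zone is None:
        zone = utm_zone(longitude)
    lam0 = math.radians((zone - 1) * 6 - 180 + 3)
    phi = math.radians(latitude)
    lam = math.radians(longitude)
    n = _A / math.sqrt(1 - _E2 * math.sin(phi) ** 2)
    t = math.tan(phi) ** 2
    c = _EP2 * math.cos(phi) ** 2
    a = (lam - lam0) * math.cos(phi)
    m = _meridian_arc(phi)
    easting = _K0 * n * (
        a + (1 - t + c) * a ** 3 / 6
        + (5 - 18 * t + t ** 2 + 72 * c - 58 * _EP2) * a ** 5 / 120
    ) + _FALSE_EASTING
    northing = _K0 * (
        m + n * math.tan(phi) * (
            a ** 2 / 2 + (5 - t + 9 * c + 4 * c ** 2) * a ** 4 / 24
            + (61 - 58 * t + t ** 2 + 600 * c - 330 * _EP2) * a ** 6 / 720
        )
    )
    if latitude < 0:
        northing += _FALSE_NORTHING_S
    return easting, northing, zone


def utm_to_latlon(easting: float, northing: float, zone: int,
                  southern: bool) -> tuple[float, float]:
    """Inverse transverse Mercator projection (footpoint-latitude
    series)."""
    x = easting - _FALSE_EASTING
    y = northing - (_FALSE_NORTHING_S if southern else 0.0)
    lam0 = math.radians((zone - 1) * 6 - 180 + 3)
    m = y / _K0
    mu = m / (_A * (1 - _E2 / 4 - 3 * _E2 ** 2 / 64 - 5 * _E2 ** 3 / 256))
    e1 = (1 - math.sqrt(1 - _E2)) / (1 + math.sqrt(1 - _E2))
    phi1 = (
        mu
        + (3 * e1 / 2 - 27 * e1 ** 3 / 32) * math.sin(2 * mu)
        + (21 * e1 ** 2 / 16 - 55 * e1 ** 4 / 32) * math.sin(4 * mu)
        + (151 * e1 ** 3 / 96) * math.sin(6 * mu)
        + (1097 * e1 ** 4 / 512) * math.sin(8 * mu)
    )
    c1 = _EP2 * math.cos(phi1) ** 2
    t1 = math.tan(phi1) ** 2
    n1 = _A / math.sqrt(1 - _E2 * math.sin(phi1) ** 2)
    r1 = _A * (1 - _E2) / (1 - _E2 * math.sin(phi1) ** 2) ** 1.5
    d = x / (n1 * _K0)
    phi = phi1 - (n1 * math.tan(phi1) / r1) * (
        d ** 2 / 2
        - (5 + 3 * t1 + 10 * c1 - 4 * c1 ** 2 - 9 * _EP2) * d ** 4 / 24
        + (61 + 90 * t1 + 298 * c1 + 45 * t1 ** 2 - 252 * _EP2
           - 3 * c1 ** 2) * d ** 6 / 720
    )
    lam = lam0 + (
        d - (1 + 2 * t1 + c1) * d ** 3 / 6
        + (5 - 2 * c1 + 28 * t1 - 3 * c1 ** 2 + 8 * _EP2
           + 24 * t1 ** 2) * d ** 5 / 120
    ) / math.cos(phi1)
    return math.degrees(phi), math.degrees(lam)


def project_positions(metadata: pd.DataFrame,
                      method: str = "utm") -> tuple[pd.DataFrame, dict]:
    """Project sample latitude/longitude columns to planar meters.

    ``method`` is "utm" (transverse Mercator in the points' UTM zone) or
    "equirectangular" (local tangent-plane approximation about the
    centroid). Samples with missing coordinates are excluded with a
    warning. Returns an (x, y) frame and projection metadata.
    """
    coords = metadata[["latitude", "longitude"]].astype(float)
    ok = coords.notna().all(axis=1)
    if (~ok).any():
        logger.warning("excluding %d samples without GPS coordinates: %s",
                       int((~ok).sum()), list(coords.index[~ok]))
    coords = coords.loc[ok]
    if coords.empty:
        raise ValueError("no samples with coordinates")
    if method == "utm":
        zone = utm_zone(float(coords["longitude"].mean()))
        xy = [latlon_to_utm(lat, lon, zone)[:2]
              for lat, lon in coords.itertuples(index=False)]
        info = {"method": "utm", "zone": zone,
                "hemisphere": "S" if coords["latitude"].mean() < 0 else "N"}
    elif method == "equirectangular":
        lat0 = float(coords["latitude"].mean())
        lon0 = float(coords["longitude"].mean())
        coslat = math.cos(math.radians(lat0))
        xy = [(_MEAN_RADIUS * math.radians(lon - lon0) * coslat,
               _MEAN_RADIUS * math.radians(lat - lat0))
              for lat, lon in coords.itertuples(index=False)]
        info = {"method": "equirectangular", "origin": (lat0, lon0)}
    else:
        raise ValueError(f"unknown projection method {method!r}")
    frame = pd.DataFrame(xy, index=coords.index, columns=["x", "y"])
    return frame, info


def geographic_distance(positions: pd.DataFrame) -> DistanceMatrix:
    """Euclidean distances (meters) between projected positions."""
    d = squareform(pdist(positions[["x", "y"]].to_numpy()))
    return DistanceMatrix(d, ids=list(positions.index))


@dataclass(frozen=True)
class MantelResult:
    r: float
    p_value: float
    n_permutations: int
    seed: int | None
    alternative: str


def mantel(d_geo: DistanceMatrix, d_comm: DistanceMatrix,
           permutations: int | str = 999, seed: int | None = None,
           alternative: str = "greater") -> MantelResult:
    """Mantel test between two distance matrices sharing ids.

    r is the Pearson correlation of the lower triangles; p comes from
    simultaneous row/column permutation of one matrix,
    p = (#{r_perm >= r_obs} + 1) / (n_perm + 1) for the default
    one-tailed (positive autocorrelation) alternative. Passing
    ``permutations="exact"`` enumerates all n! relabelings.
    """
    if list(d_geo.ids) != list(d_comm.ids):
        if set(d_geo.ids) != set(d_comm.ids):
            raise ValueError("distance matrices have different sample sets")
        d_comm = d_comm.filter(d_geo.ids)
    n = len(d_geo.ids)
    if n < 4:
        raise ValueError("Mantel test needs at least 4 samples")
    iu = np.triu_indices(n, k=1)
    a = d_geo.data[iu]
    b_mat = d_comm.data
    b = b_mat[iu]
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance in a distance matrix")
    az = (a - a.mean()) / a.std()

    def corr(bvec: np.ndarray) -> float:
        return float(np.dot(az, (bvec - bvec.mean()) / bvec.std()) / len(a))

    r_obs = corr(b)

    def effect(r: float) -> float:
        if alternative == "greater":
            return r
        if alternative == "less":
            return -r
        return abs(r)

    if permutations == "exact":
        if n > 9:
            raise ValueError("exact enumeration is limited to n <= 9")
        perms = list(itertools.permutations(range(n)))
        count = sum(
            effect(corr(b_mat[np.ix_(p, p)][iu])) >= effect(r_obs) - 1e-12
            for p in perms)
        return MantelResult(r_obs, count / len(perms), len(perms), None,
                            alternative)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(int(permutations)):
        idx = rng.permutation(n)
        r_p = corr(b_mat[np.ix_(idx, idx)][iu])
        if effect(r_p) >= effect(r_obs) - 1e-12:
            count += 1
    p = (count + 1) / (int(permutations) + 1)
    return MantelResult(r_obs, p, int(permutations), seed, alternative)
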