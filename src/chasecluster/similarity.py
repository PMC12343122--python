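"""Pairwise compositional similarity (the chase matrix) and great-circle geometry."""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .community_data import Site, SiteMatrix
from .errors import DomainError, SizeError

#: IUGG mean Earth radius, km — fixed so distances are bit-reproducible.
EARTH_RADIUS_KM = 6371.0088

METRICS = ("jaccard", "simpson", "ochiai")


@dataclass
class ChaseMatrix:
    """Symmetric pairwise compositional similarity among sites, entries in [0,1]."""

    site_ids: list[str]
    S: np.ndarray
    metric: str = "jaccard"

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        n = len(self.site_ids)
        if self.S.shape != (n, n):
            raise ValueError("S shape does not match site_ids")
        if not np.allclose(self.S, self.S.T):
            raise ValueError("S must be symmetric")
        if not np.allclose(np.diag(self.S), 1.0):
            raise ValueError("S diagonal must be 1")
        if self.S.min() < -1e-12 or self.S.max() > 1 + 1e-12:
            raise ValueError("S entries must lie in [0,1]")

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)


@dataclass
class GeoMatrix:
    """Symmetric great-circle distances among sites, kilometres."""

    site_ids: list[str]
    D: np.ndarray

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        n = len(self.site_ids)
        if self.D.shape != (n, n):
            raise ValueError("D shape does not match site_ids")
        if not np.allclose(self.D, self.D.T):
            raise ValueError("D must be symmetric")
        if self.D.min() < 0 or self.D.max() > np.pi * EARTH_RADIUS_KM + 1e-6:
            raise ValueError("distances out of range")


def pair_similarity(a: frozenset | set, b: frozenset | set, metric: str = "jaccard") -> float:
    """Compositional similarity of two species sets.

    jaccard = |a∩b|/|a∪b|; simpson = |a∩b|/min(|a|,|b|); ochiai = |a∩b|/√(|a||b|).
    """
    if not a or not b:
        raise DomainError("species sets must be non-empty")
    inter = len(a & b)
    if metric == "jaccard":
        return inter / len(a | b)
    if metric == "simpson":
        return inter / min(len(a), len(b))
    if metric == "ochiai":
        return inter / np.sqrt(len(a) * len(b))
    raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")


def chase_matrix(matrix: SiteMatrix, metric: str = "jaccard") -> ChaseMatrix:
    """All-pairs similarity matrix over a filtered incidence matrix."""
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    n = matrix.n_sites
    if n < 2:
        raise SizeError("need at least 2 sites for a chase matrix")
    richness = matrix.richness().astype(float)
    if (richness == 0).any():
        raise DomainError("empty sites present; apply the richness filter first")
    B = matrix.incidence.astype(float)
    inter = B @ B.T
    if metric == "jaccard":
        union = richness[:, None] + richness[None, :] - inter
        S = inter / union
    elif metric == "simpson":
        S = inter / np.minimum(richness[:, None], richness[None, :])
    else:  # ochiai
        S = inter / np.sqrt(richness[:, None] * richness[None, :])
    np.fill_diagonal(S, 1.0)
    S = np.clip(S, 0.0, 1.0)
    S = (S + S.T) / 2.0
    return ChaseMatrix(site_ids=list(matrix.site_ids), S=S, metric=metric)


def _check_coord(lat: float, lon: float) -> None:
    if not (np.isfinite(lat) and -90.0 <= lat <= 90.0):
        raise DomainError(f"latitude out of range: {lat}")
    if not (np.isfinite(lon) and -180.0 <= lon <= 180.0):
        raise DomainError(f"longitude out of range: {lon}")


def great_circle_km(p: tuple[float, float], q: tuple[float, float]) -> float:
    """Haversine great-circle distance in km between (lat, lon) points."""
    _check_coord(*p)
    _check_coord(*q)
    lat1, lon1, lat2, lon2 = map(np.radians, (p[0], p[1], q[0], q[1]))
    a = (np.sin((lat2 - lat1) / 2) ** 2
         + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2)
    return float(2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0))))


def _pairwise_haversine(coords: np.ndarray) -> np.ndarray:
    lat = np.radians(coords[:, 0])[:, None]
    lon = np.radians(coords[:, 1])[:, None]
    a = (np.sin((lat.T - lat) / 2) ** 2
         + np.cos(lat) * np.cos(lat.T) * np.sin((lon.T - lon) / 2) ** 2)
    D = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    np.fill_diagonal(D, 0.0)
    return (D + D.T) / 2.0


def geo_matrix(sites: Sequence[Site] | SiteMatrix) -> GeoMatrix:
    """Pairwise great-circle distances for a list of sites or a SiteMatrix."""
    if isinstance(sites, SiteMatrix):
        ids, coords = list(sites.site_ids), sites.coords
    else:
        ids = [s.site_id for s in sites]
        coords = np.array([(s.latitude, s.longitude) for s in sites], dtype=float)
    if len(ids) < 2:
        raise SizeError("need at least 2 sites for a distance matrix")
    for lat, lon in coords:
        _check_coord(lat, lon)
    return GeoMatrix(site_ids=ids, D=_pairwise_haversine(coords))
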