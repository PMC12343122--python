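"""Synthetic incidence matrices with planted regional structure.

The generator emulates the structure of a global zooarchaeological
compilation: several regional species pools with limited overlap
(cross-region "leakage" plus a cosmopolitan pool), per-site Bernoulli
detection of pool members, a cross-regional domesticate overlay that
homogenizes otherwise distinct regions, and epoch pairs whose regional pools
are partially replaced so the expected Jaccard turnover is known in closed
form. True region labels are returned for recovery tests.

All randomness flows from one integer seed through named substreams (pools,
sites, coordinates, domesticates, epochs), so individual components can be
regenerated independently.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .community_data import OccurrenceRecord, Site, SiteMatrix
from .errors import ConfigError

# default centers: five continental-scale points, pairwise far beyond
# 10 * coord_sd so the geographic signal is separable
_DEFAULT_CENTERS = (
    (45.0, -100.0),   # North America
    (-15.0, -60.0),   # South America
    (48.0, 15.0),     # Europe
    (0.0, 25.0),      # Africa
    (-25.0, 135.0),   # Australia
)

_STREAMS = {"pools": 0, "sites": 1, "coordinates": 2, "domesticates": 3,
            "epochs": 4}


@dataclass(frozen=True)
class SyntheticConfig:
    """Planted-partition community generator settings.

    n_regions regional pools of species_per_region species each (disjoint by
    construction) plus n_cosmopolitan shared species. Each of sites_per_region
    sites per region detects its own pool members with probability p_det,
    cosmopolitans with p_cos, and foreign-pool species with p_leak.
    Domesticate overlay: n_domesticates extra taxa, each present at any site
    with probability p_dom regardless of region. Epoch pairs replace a
    tau_loss fraction of each regional pool and add tau_gain * B novel
    species, giving expected pool-level Jaccard turnover
    (tau_loss + tau_gain) / (1 + tau_gain).
    """

    n_regions: int = 5
    species_per_region: int = 40
    n_cosmopolitan: int = 10
    sites_per_region: int = 12
    p_det: float = 0.6
    p_cos: float = 0.3
    p_leak: float = 0.02
    n_domesticates: int = 6
    p_dom: float = 0.5
    region_centers: Optional[tuple[tuple[float, float], ...]] = None
    coord_sd: float = 1.5
    tau_loss: float = 0.2
    tau_gain: float = 0.2
    min_richness: int = 5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_det", "p_cos", "p_leak", "p_dom", "tau_loss", "tau_gain"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0,1], got {v}")
        if self.n_regions < 2:
            raise ConfigError("n_regions must be >= 2")
        if self.tau_loss + self.tau_gain > 1.0 + 1e-12:
            raise ConfigError("tau_loss + tau_gain must be <= 1")
        centers = self.centers()
        if len(centers) < self.n_regions:
            raise ConfigError("need one region center per region")
        # separability of the geographic signal
        for a in range(self.n_regions):
            for b in range(a + 1, self.n_regions):
                d = np.hypot(centers[a][0] - centers[b][0],
                             centers[a][1] - centers[b][1])
                if d < 10 * self.coord_sd:
                    raise ConfigError(
                        f"region centers {a} and {b} closer than 10*coord_sd")

    def centers(self) -> tuple[tuple[float, float], ...]:
        if self.region_centers is not None:
            return self.region_centers
        if self.n_regions <= len(_DEFAULT_CENTERS):
            return _DEFAULT_CENTERS[: self.n_regions]
        raise ConfigError("region_centers required when n_regions > 5")

    def rng(self, stream: str, extra: int = 0) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([self.rng_seed, _STREAMS[stream], extra]))


def _region_taxa(g: int, count: int, prefix: str = "sp") -> list[str]:
    return [f"{prefix}_r{g + 1}_{j + 1:03d}" for j in range(count)]


def _site_matrix_from_incidence(site_ids, taxon_ids, inc, coords) -> SiteMatrix:
    order = np.argsort(site_ids)
    t_order = np.argsort(taxon_ids)
    inc = inc[np.ix_(order, t_order)]
    keep = inc.sum(axis=0) > 0
    sorted_taxa = [taxon_ids[j] for j in t_order]
    return SiteMatrix(
        site_ids=[site_ids[i] for i in order],
        taxon_ids=[t for t, k in zip(sorted_taxa, keep) if k],
        incidence=inc[:, keep],
        coords=coords[order],
    )


def _draw_site_row(rng, n_taxa, region_cols, cos_cols, p_det, p_cos, p_leak,
                   min_richness, max_attempts: int = 100) -> np.ndarray:
    own = np.zeros(n_taxa, dtype=bool)
    own[region_cols] = True
    cos = np.zeros(n_taxa, dtype=bool)
    cos[cos_cols] = True
    foreign = ~(own | cos)
    for _ in range(max_attempts):
        u = rng.random(n_taxa)
        row = (own & (u < p_det)) | (cos & (u < p_cos)) | (foreign & (u < p_leak))
        if row.sum() >= min_richness:
            return row.astype(np.int8)
    raise ConfigError(
        f"could not draw a site with >= {min_richness} species in "
        f"{max_attempts} attempts; detection probabilities too low")


def simulate_sites(cfg: SyntheticConfig = SyntheticConfig()
                   ) -> tuple[SiteMatrix, np.ndarray]:
    """Planted-region incidence matrix and true region labels.

    Each site re-draws (up to 100 attempts) until it holds at least
    cfg.min_richness species, so the matrix is analysis-ready without
    further filtering. Labels are aligned to the (lexicographically sorted)
    site order of the returned matrix.
    """
    G, B, C, S = (cfg.n_regions, cfg.species_per_region,
                  cfg.n_cosmopolitan, cfg.sites_per_region)
    taxa = [t for g in range(G) for t in _region_taxa(g, B)]
    taxa += [f"sp_cos_{j + 1:03d}" for j in range(C)]
    n_taxa = len(taxa)
    cos_cols = np.arange(G * B, n_taxa)

    site_ids, labels, rows, coords = [], [], [], []
    rng_sites = cfg.rng("sites")
    rng_coords = cfg.rng("coordinates")
    centers = cfg.centers()
    for g in range(G):
        region_cols = np.arange(g * B, (g + 1) * B)
        for s in range(S):
            site_ids.append(f"r{g + 1}_site{s + 1:02d}")
            labels.append(g)
            rows.append(_draw_site_row(
                rng_sites, n_taxa, region_cols, cos_cols,
                cfg.p_det, cfg.p_cos, cfg.p_leak, cfg.min_richness))
            lat = np.clip(centers[g][0] + rng_coords.normal(0, cfg.coord_sd), -90, 90)
            lon = centers[g][1] + rng_coords.normal(0, cfg.coord_sd)
            lon = (lon + 180.0) % 360.0 - 180.0
            coords.append((lat, lon))

    inc = np.array(rows, dtype=np.int8)
    order = np.argsort(site_ids)
    matrix = _site_matrix_from_incidence(
        site_ids, taxa, inc, np.array(coords, dtype=float))
    return matrix, np.array(labels)[order]


def overlay_domesticates(matrix: SiteMatrix,
                         cfg: SyntheticConfig = SyntheticConfig()
                         ) -> SiteMatrix:
    """Add the cross-regional domesticate columns (the homogenizing signal).

    Each site acquires each of cfg.n_domesticates new taxa independently
    with probability cfg.p_dom, regardless of region. Empty columns are
    dropped, so p_dom = 0 returns the input unchanged.
    """
    rng = cfg.rng("domesticates")
    dom_taxa = [f"dom_{j + 1:02d}" for j in range(cfg.n_domesticates)]
    dom = (rng.random((matrix.n_sites, cfg.n_domesticates)) < cfg.p_dom
           ).astype(np.int8)
    inc = np.hstack([matrix.incidence, dom])
    taxa = list(matrix.taxon_ids) + dom_taxa
    return _site_matrix_from_incidence(
        list(matrix.site_ids), taxa, inc, matrix.coords.copy())


def domesticate_names(cfg: SyntheticConfig = SyntheticConfig()) -> set[str]:
    return {f"dom_{j + 1:02d}" for j in range(cfg.n_domesticates)}


def expected_pool_turnover(cfg: SyntheticConfig) -> float:
    """Closed-form expected pool-level Jaccard turnover between epochs:
    (lost + gained) / (B + gained) with the realized integer fractions."""
    n_lost = int(np.floor(cfg.tau_loss * cfg.species_per_region))
    n_new = int(np.floor(cfg.tau_gain * cfg.species_per_region))
    return (n_lost + n_new) / (cfg.species_per_region + n_new)


def simulate_epoch_pair(cfg: SyntheticConfig = SyntheticConfig()
                        ) -> tuple[SiteMatrix, SiteMatrix, np.ndarray]:
    """Pleistocene/Holocene matrices with controlled pool turnover.

    The Holocene pool of each region drops a uniform-random floor(tau_loss*B)
    subset of the Pleistocene pool and adds floor(tau_gain*B) novel species.
    Expected pool-level Jaccard turnover, returned per region, is
    (tau_loss + tau_gain) / (1 + tau_gain) (with the realized integer
    fractions). Both epochs share region centers, so 50 km aggregation can
    pair their sites.
    """
    G, B, C, S = (cfg.n_regions, cfg.species_per_region,
                  cfg.n_cosmopolitan, cfg.sites_per_region)
    rng_pool = cfg.rng("epochs")
    n_lost = int(np.floor(cfg.tau_loss * B))
    n_new = int(np.floor(cfg.tau_gain * B))

    # region pools: Pleistocene = base; Holocene = base - lost + novel
    base = [_region_taxa(g, B) for g in range(G)]
    novel = [_region_taxa(g, n_new, prefix="nsp") for g in range(G)]
    holo_pool = []
    for g in range(G):
        lost = set(rng_pool.choice(B, size=n_lost, replace=False))
        holo_pool.append([t for j, t in enumerate(base[g]) if j not in lost]
                         + novel[g])
    expected = np.full(G, expected_pool_turnover(cfg))

    cos = [f"sp_cos_{j + 1:03d}" for j in range(C)]
    centers = cfg.centers()

    def build(epoch_tag: str, pools: list[list[str]], stream_extra: int) -> SiteMatrix:
        taxa = sorted({t for p in pools for t in p} | set(cos))
        t_index = {t: j for j, t in enumerate(taxa)}
        rng_sites = cfg.rng("sites", extra=stream_extra)
        rng_coords = cfg.rng("coordinates", extra=stream_extra)
        site_ids, rows, coords = [], [], []
        for g in range(G):
            region_cols = np.array([t_index[t] for t in pools[g]], dtype=np.intp)
            cos_cols = np.array([t_index[t] for t in cos], dtype=np.intp)
            for s in range(S):
                site_ids.append(f"{epoch_tag}_r{g + 1}_site{s + 1:02d}")
                rows.append(_draw_site_row(
                    rng_sites, len(taxa), region_cols, cos_cols,
                    cfg.p_det, cfg.p_cos, cfg.p_leak, cfg.min_richness))
                lat = np.clip(centers[g][0] + rng_coords.normal(0, cfg.coord_sd),
                              -90, 90)
                lon = centers[g][1] + rng_coords.normal(0, cfg.coord_sd)
                coords.append((lat, (lon + 180.0) % 360.0 - 180.0))
        return _site_matrix_from_incidence(
            site_ids, taxa, np.array(rows, dtype=np.int8),
            np.array(coords, dtype=float))

    pleis = build("p", base, stream_extra=10)
    holo = build("h", holo_pool, stream_extra=11)
    return pleis, holo, expected


def simulate_nested_sites(
    n_super: int = 2,
    n_sub: int = 3,
    sites_per_sub: int = 6,
    shared_per_super: int = 8,
    species_per_sub: int = 30,
    p_det: float = 0.95,
    min_richness: int = 5,
    rng_seed: int = 0,
) -> tuple[SiteMatrix, np.ndarray, np.ndarray]:
    """Two-level (hierarchical) planted structure for regularization sweeps.

    Each super-region holds a small pool shared by all its subregions plus a
    private pool per subregion; super-regions are disjoint. Expected
    cross-subregion Jaccard within a super-region is roughly
    shared / (shared + 2 * private), so a regularization sweep transitions
    from merging whole super-regions to isolating subregions. Returns
    (matrix, super labels, subregion labels), label arrays aligned to the
    matrix's site order.
    """
    rng = np.random.default_rng(np.random.SeedSequence([rng_seed, 97]))
    taxa, pools = [], {}
    for a in range(n_super):
        shared = [f"shr_s{a + 1}_{j + 1:03d}" for j in range(shared_per_super)]
        taxa += shared
        for b in range(n_sub):
            private = [f"sp_s{a + 1}_u{b + 1}_{j + 1:03d}"
                       for j in range(species_per_sub)]
            taxa += private
            pools[(a, b)] = shared + private
    t_index = {t: j for j, t in enumerate(taxa)}

    site_ids, sup_lab, sub_lab, rows = [], [], [], []
    centers_lat = np.linspace(-40, 40, n_super * n_sub)
    coords = []
    ci = 0
    for a in range(n_super):
        for b in range(n_sub):
            cols = np.array([t_index[t] for t in pools[(a, b)]])
            for s in range(sites_per_sub):
                site_ids.append(f"s{a + 1}_u{b + 1}_site{s + 1:02d}")
                sup_lab.append(a)
                sub_lab.append(a * n_sub + b)
                for _ in range(100):
                    row = np.zeros(len(taxa), dtype=np.int8)
                    row[cols] = (rng.random(len(cols)) < p_det).astype(np.int8)
                    if row.sum() >= min_richness:
                        break
                rows.append(row)
                coords.append((centers_lat[ci], 10.0 * ci + rng.normal(0, 0.5)))
            ci += 1

    matrix = _site_matrix_from_incidence(
        site_ids, taxa, np.array(rows, dtype=np.int8),
        np.array(coords, dtype=float))
    order = np.argsort(site_ids)
    return matrix, np.array(sup_lab)[order], np.array(sub_lab)[order]


def realized_region_turnover(pleistocene: SiteMatrix, holocene: SiteMatrix,
                             cfg: SyntheticConfig) -> np.ndarray:
    """Realized pool-level Jaccard turnover per region.

    Pools each region's detected species across its sites (site ids carry the
    region tag ``r<g>``) and measures the Jaccard distance between epochs —
    the quantity whose expectation ``simulate_epoch_pair`` returns in closed
    form. Meaningful as a calibration of the pool-replacement mechanism when
    cross-region leakage is off (p_leak = 0); leakage is a separate overlap
    channel not described by the closed form.
    """
    from .turnover import turnover_jaccard

    out = []
    for g in range(cfg.n_regions):
        tag = f"_r{g + 1}_"
        p_rows = [i for i, s in enumerate(pleistocene.site_ids) if tag in s]
        h_rows = [i for i, s in enumerate(holocene.site_ids) if tag in s]
        t = turnover_jaccard(pleistocene.species_union(p_rows),
                             holocene.species_union(h_rows))
        out.append(t["jaccard_distance"])
    return np.array(out)


# ---------------------------------------------------------------------------
# Export to the occurrence/site file formats community_data reads
# ---------------------------------------------------------------------------

def to_records(matrix: SiteMatrix, epoch: str,
               domesticates: Optional[set[str]] = None
               ) -> tuple[list[OccurrenceRecord], list[Site]]:
    """Round-trippable long-form records and site table for a matrix."""
    domesticates = domesticates or set()
    records = [
        OccurrenceRecord(site_id=s, taxon=t, epoch=epoch, rank="species",
                         nisp=1, is_domesticate=t in domesticates)
        for i, s in enumerate(matrix.site_ids)
        for j, t in enumerate(matrix.taxon_ids)
        if matrix.incidence[i, j]
    ]
    sites = [
        Site(site_id=s, name=s, latitude=float(matrix.coords[i, 0]),
             longitude=float(matrix.coords[i, 1]), epoch=epoch)
        for i, s in enumerate(matrix.site_ids)
    ]
    return records, sites
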