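"""Reading, validating, filtering and reshaping occurrence data.

Long-form occurrence tables (one row per site x taxon observation) and site
coordinate tables are turned into binary site-by-species incidence matrices
(`SiteMatrix`), the exchange object every downstream analysis consumes.

Orientation: sites are rows internally and in the wide-matrix interchange
format. Row and column order is lexicographic everywhere, so matrices are
invariant to input record order and downstream stochastic runs see a stable
site ordering.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (
    EmptyInputError,
    FormatError,
    ReferentialIntegrityError,
)

logger = logging.getLogger(__name__)

RANKS = frozenset({"species", "genus", "family", "unranked"})
EPOCHS = frozenset({"pleistocene", "holocene"})

_TRUE_STRINGS = {"true", "1", "yes", "t", "y"}
_FALSE_STRINGS = {"false", "0", "no", "f", "n", ""}


@dataclass(frozen=True)
class OccurrenceRecord:
    """One taxon observed at one site in one epoch.

    ``nisp`` (number of identified specimens) is carried through but reduced
    to presence-absence when matrices are built; when present it must be >= 1.
    """

    site_id: str
    taxon: str
    epoch: str
    rank: str = "species"
    nisp: Optional[int] = None
    is_domesticate: bool = False

    def __post_init__(self) -> None:
        if self.rank not in RANKS:
            raise ValueError(f"unknown rank {self.rank!r}")
        if self.epoch not in EPOCHS:
            raise ValueError(f"unknown epoch {self.epoch!r}")
        if self.nisp is not None and self.nisp < 1:
            raise ValueError(f"nisp must be >= 1, got {self.nisp}")


@dataclass(frozen=True)
class Site:
    """A dated assemblage location with WGS84 decimal-degree coordinates."""

    site_id: str
    name: str
    latitude: float
    longitude: float
    epoch: str

    def __post_init__(self) -> None:
        if self.epoch not in EPOCHS:
            raise ValueError(f"unknown epoch {self.epoch!r}")
        if not (np.isfinite(self.latitude) and -90.0 <= self.latitude <= 90.0):
            raise ValueError(f"latitude out of range: {self.latitude}")
        if not (np.isfinite(self.longitude) and -180.0 <= self.longitude <= 180.0):
            raise ValueError(f"longitude out of range: {self.longitude}")


@dataclass(frozen=True)
class FilterConfig:
    """Richness filtering options.

    min_richness: minimum number of species a site must hold to be retained
    (default 5 -- sites with fewer species carry unstable compositional
    signal). drop_domesticates: whether downstream "wild" analyses remove
    domesticate columns before re-filtering.
    """

    min_richness: int = 5
    drop_domesticates: bool = False

    def __post_init__(self) -> None:
        if self.min_richness < 1:
            raise ValueError("min_richness must be >= 1")


@dataclass
class SiteMatrix:
    """Binary site-by-species incidence with aligned coordinates.

    Rows are sites, columns taxa, both lexicographically ordered; entries are
    0/1; coords[i] = (latitude, longitude) of site_ids[i].
    """

    site_ids: list[str]
    taxon_ids: list[str]
    incidence: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.incidence = np.asarray(self.incidence, dtype=np.int8)
        self.coords = np.asarray(self.coords, dtype=float)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        n, m = self.incidence.shape
        if len(self.site_ids) != n or len(self.taxon_ids) != m:
            raise ValueError("id lists do not match incidence shape")
        if len(set(self.site_ids)) != n:
            raise ValueError("duplicate site ids")
        if len(set(self.taxon_ids)) != m:
            raise ValueError("duplicate taxon ids")
        if self.coords.shape != (n, 2):
            raise ValueError("coords must be (n_sites, 2)")
        if not np.isin(self.incidence, (0, 1)).all():
            raise ValueError("incidence entries must be 0/1")

    # -- convenience ------------------------------------------------------
    @property
    def n_sites(self) -> int:
        return self.incidence.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.incidence.shape[1]

    def richness(self) -> np.ndarray:
        """Per-site species counts (row sums)."""
        return self.incidence.sum(axis=1)

    def species_set(self, i: int) -> frozenset[str]:
        row = self.incidence[i]
        return frozenset(t for t, v in zip(self.taxon_ids, row) if v)

    def species_union(self, rows: Iterable[int]) -> frozenset[str]:
        rows = list(rows)
        if not rows:
            return frozenset()
        mask = self.incidence[rows].any(axis=0)
        return frozenset(t for t, v in zip(self.taxon_ids, mask) if v)

    def subset_sites(self, keep: np.ndarray) -> "SiteMatrix":
        """Rows restricted to boolean/index mask ``keep``; zero columns dropped."""
        inc = self.incidence[keep]
        ids = [s for s, k in zip(self.site_ids, np.asarray(keep)) if k] \
            if np.asarray(keep).dtype == bool else [self.site_ids[i] for i in keep]
        coords = self.coords[keep]
        col_keep = inc.sum(axis=0) > 0
        return SiteMatrix(
            site_ids=ids,
            taxon_ids=[t for t, k in zip(self.taxon_ids, col_keep) if k],
            incidence=inc[:, col_keep],
            coords=coords,
        )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_OCC_MANDATORY = ("site_id", "taxon", "epoch")
_SITE_MANDATORY = ("site_id", "name", "latitude", "longitude", "epoch")


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise EmptyInputError(f"{path} is empty")
    # comma default, tab accepted
    df = pd.read_csv(path, sep=None, engine="python", dtype=str,
                     keep_default_na=False)
    if df.empty:
        raise EmptyInputError(f"{path} contains a header but no rows")
    df.columns = [c.strip().lower() for c in df.columns]
    return df


def _parse_bool(value: str) -> bool:
    v = value.strip().lower()
    if v in _TRUE_STRINGS:
        return True
    if v in _FALSE_STRINGS:
        return False
    raise ValueError(f"cannot parse boolean {value!r}")


def read_occurrences(path: str | Path, strict: bool = False) -> list[OccurrenceRecord]:
    """Read a long-form occurrence table.

    Columns site_id, taxon, epoch are mandatory; rank, nisp, is_domesticate
    optional. Enum/boolean fields are normalized case-insensitively; rank
    defaults to species. Rows that violate the record invariants (e.g.
    nisp = 0) are rejected and reported with their file line numbers — as
    warnings by default, or collectively as a FormatError when ``strict``.
    """
    df = _read_table(path)
    missing = [c for c in _OCC_MANDATORY if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s): {', '.join(missing)}")

    records: list[OccurrenceRecord] = []
    problems: list[str] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        line_no = idx + 2  # header is line 1
        d = dict(zip(df.columns, row))
        try:
            nisp_raw = d.get("nisp", "").strip()
            nisp = int(nisp_raw) if nisp_raw else None
            rank = d.get("rank", "").strip().lower() or "species"
            rec = OccurrenceRecord(
                site_id=d["site_id"].strip(),
                taxon=d["taxon"].strip(),
                epoch=d["epoch"].strip().lower(),
                rank=rank,
                nisp=nisp,
                is_domesticate=_parse_bool(d.get("is_domesticate", "false")),
            )
            if not rec.site_id or not rec.taxon:
                raise ValueError("empty site_id or taxon")
        except (ValueError, KeyError) as exc:
            problems.append(f"line {line_no}: {exc}")
            continue
        records.append(rec)

    if problems:
        msg = f"{path}: rejected {len(problems)} row(s): " + "; ".join(problems)
        if strict:
            raise FormatError(msg)
        logger.warning(msg)
    return records


def read_sites(path: str | Path) -> list[Site]:
    """Read a site coordinate table (site_id, name, latitude, longitude, epoch)."""
    df = _read_table(path)
    missing = [c for c in _SITE_MANDATORY if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    sites = []
    for idx, row in enumerate(df.itertuples(index=False)):
        d = dict(zip(df.columns, row))
        try:
            sites.append(Site(
                site_id=d["site_id"].strip(),
                name=d["name"].strip(),
                latitude=float(d["latitude"]),
                longitude=float(d["longitude"]),
                epoch=d["epoch"].strip().lower(),
            ))
        except ValueError as exc:
            raise FormatError(f"{path}: line {idx + 2}: {exc}") from exc
    return sites


def write_occurrences(records: Sequence[OccurrenceRecord], path: str | Path) -> None:
    pd.DataFrame([
        {
            "site_id": r.site_id,
            "taxon": r.taxon,
            "rank": r.rank,
            "epoch": r.epoch,
            "nisp": "" if r.nisp is None else r.nisp,
            "is_domesticate": str(r.is_domesticate).lower(),
        }
        for r in records
    ]).to_csv(path, index=False)


def write_sites(sites: Sequence[Site], path: str | Path) -> None:
    pd.DataFrame([
        {
            "site_id": s.site_id,
            "name": s.name,
            "latitude": s.latitude,
            "longitude": s.longitude,
            "epoch": s.epoch,
        }
        for s in sites
    ]).to_csv(path, index=False)


def write_wide_matrix(matrix: SiteMatrix, path: str | Path) -> None:
    """Wide incidence interchange: first column site_id, then taxon columns, 0/1."""
    df = pd.DataFrame(matrix.incidence, columns=matrix.taxon_ids)
    df.insert(0, "site_id", matrix.site_ids)
    df.to_csv(path, index=False)


def read_wide_matrix(path: str | Path, sites: Sequence[Site]) -> SiteMatrix:
    """Read the wide interchange format, joining coordinates from ``sites``."""
    df = _read_table(path)
    if "site_id" not in df.columns:
        raise FormatError(f"{path}: missing mandatory column(s): site_id")
    coords_by_id = {s.site_id: (s.latitude, s.longitude) for s in sites}
    unknown = sorted(set(df["site_id"]) - set(coords_by_id))
    if unknown:
        raise ReferentialIntegrityError(
            f"sites without coordinates: {', '.join(unknown)}")
    df = df.sort_values("site_id").reset_index(drop=True)
    taxa = sorted(c for c in df.columns if c != "site_id")
    inc = df[taxa].astype(np.int8).to_numpy()
    keep = inc.sum(axis=0) > 0
    return SiteMatrix(
        site_ids=list(df["site_id"]),
        taxon_ids=[t for t, k in zip(taxa, keep) if k],
        incidence=inc[:, keep],
        coords=np.array([coords_by_id[s] for s in df["site_id"]], dtype=float),
    )


# ---------------------------------------------------------------------------
# Record-level transforms
# ---------------------------------------------------------------------------

def default_genus_of(records: Iterable[OccurrenceRecord]) -> dict[str, str]:
    """Derive a taxon -> genus mapping from names.

    Species-rank binomials map to their first whitespace-delimited token;
    genus-rank names map to themselves. Family/unranked names are absent
    from the mapping (their lineage is not resolvable from the name alone).
    """
    mapping: dict[str, str] = {}
    for r in records:
        if r.rank == "species":
            mapping[r.taxon] = r.taxon.split()[0]
        elif r.rank == "genus":
            mapping[r.taxon] = r.taxon
    return mapping


def reduce_min_unique(
    records: Sequence[OccurrenceRecord],
    genus_of: Optional[Mapping[str, str]] = None,
) -> list[OccurrenceRecord]:
    """Minimum-unique-taxa rule: keep only the most specific non-overlapping
    identifications within each site.

    A genus-rank record is dropped at a site when at least one species-rank
    record of the same genus occurs at that same site. Removal applies per
    site and per epoch, never globally. Family/unranked records pass through
    unchanged (their lineage is not resolvable here) and are logged. The
    result is sorted, hence deterministic and order-independent.
    """
    if genus_of is None:
        genus_of = default_genus_of(records)

    # genera represented by species-rank records, per (site, epoch)
    covered: dict[tuple[str, str], set[str]] = {}
    for r in records:
        if r.rank == "species":
            genus = genus_of.get(r.taxon, r.taxon.split()[0])
            covered.setdefault((r.site_id, r.epoch), set()).add(genus)

    out: list[OccurrenceRecord] = []
    passed_through = 0
    for r in records:
        if r.rank == "genus":
            genus = genus_of.get(r.taxon, r.taxon)
            if genus in covered.get((r.site_id, r.epoch), ()):
                continue
        elif r.rank in ("family", "unranked"):
            passed_through += 1
        out.append(r)
    if passed_through:
        logger.info(
            "reduce_min_unique: %d family/unranked record(s) passed through "
            "unchanged (lineage not resolvable)", passed_through)
    out.sort(key=lambda r: (r.site_id, r.taxon, r.rank, r.epoch))
    return out


# ---------------------------------------------------------------------------
# Matrix construction and filtering
# ---------------------------------------------------------------------------

def build_matrix(
    records: Sequence[OccurrenceRecord],
    sites: Sequence[Site],
    epoch: str,
) -> SiteMatrix:
    """Presence-absence incidence for one epoch.

    incidence[i, j] = 1 iff at least one record of taxon j exists at site i;
    NISP counts are discarded. Only sites with at least one record appear as
    rows; taxa with no occurrences are absent. Rows and columns are sorted
    lexicographically.
    """
    if epoch not in EPOCHS:
        raise ValueError(f"unknown epoch {epoch!r}")
    epoch_sites = {s.site_id: s for s in sites if s.epoch == epoch}
    if len(epoch_sites) != sum(1 for s in sites if s.epoch == epoch):
        raise ValueError(f"duplicate site_id within epoch {epoch}")
    recs = [r for r in records if r.epoch == epoch]
    unknown = sorted({r.site_id for r in recs} - set(epoch_sites))
    if unknown:
        raise ReferentialIntegrityError(
            f"records reference unknown site id(s) for epoch {epoch}: "
            + ", ".join(unknown))
    if not recs:
        raise EmptyInputError(f"no records for epoch {epoch}")

    site_ids = sorted({r.site_id for r in recs})
    taxon_ids = sorted({r.taxon for r in recs})
    s_index = {s: i for i, s in enumerate(site_ids)}
    t_index = {t: j for j, t in enumerate(taxon_ids)}
    inc = np.zeros((len(site_ids), len(taxon_ids)), dtype=np.int8)
    for r in recs:
        inc[s_index[r.site_id], t_index[r.taxon]] = 1
    coords = np.array(
        [(epoch_sites[s].latitude, epoch_sites[s].longitude) for s in site_ids],
        dtype=float)
    return SiteMatrix(site_ids=site_ids, taxon_ids=taxon_ids,
                      incidence=inc, coords=coords)


def filter_richness(matrix: SiteMatrix, config: FilterConfig) -> SiteMatrix:
    """Drop sites with fewer than ``config.min_richness`` species, then drop
    taxa left with zero occurrences. Idempotent (column removal cannot lower
    any remaining row sum)."""
    keep = matrix.richness() >= config.min_richness
    if not keep.any():
        raise EmptyInputError(
            f"all {matrix.n_sites} sites fall below min_richness="
            f"{config.min_richness}")
    if keep.all():
        return matrix
    return matrix.subset_sites(keep)


def split_domesticates(
    matrix: SiteMatrix,
    domesticates: set[str],
    config: FilterConfig = FilterConfig(),
) -> tuple[SiteMatrix, SiteMatrix]:
    """Return (wild, all) matrices.

    ``all`` is the input unchanged. ``wild`` drops the domesticate columns and
    re-applies the richness filter with the same configuration, so sites whose
    assemblage was carried by domesticates fall out. Domesticate names absent
    from the matrix are warnings, not errors (one list can serve both epochs).
    """
    unknown = sorted(domesticates - set(matrix.taxon_ids))
    if unknown:
        logger.warning("domesticate name(s) not in matrix: %s", ", ".join(unknown))
    col_keep = np.array([t not in domesticates for t in matrix.taxon_ids])
    wild = SiteMatrix(
        site_ids=list(matrix.site_ids),
        taxon_ids=[t for t, k in zip(matrix.taxon_ids, col_keep) if k],
        incidence=matrix.incidence[:, col_keep],
        coords=matrix.coords.copy(),
    )
    wild = filter_richness(wild, config)
    return wild, matrix
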