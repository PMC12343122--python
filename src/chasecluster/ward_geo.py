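"""Geography-constrained Ward clustering via an alpha-mixed dissimilarity.

Two dissimilarity matrices are combined convexly: D0, the Euclidean distance
between binary occupancy rows (= sqrt of the symmetric-difference size), and
D1, great-circle distances in km. Both are first normalized by their maximum
off-diagonal entry so the mixing weight alpha is interpretable on [0,1]:
alpha = 0 is pure composition, alpha = 1 pure geography. Ward agglomeration
(own Lance-Williams implementation, deterministic tie-breaking by lowest
cluster index) builds a dendrogram; cutting it at a fixed k — typically the
k selected by chase clustering — yields the constrained partition. When
alpha = "auto", a grid of alphas (step 0.01) is scanned and the value
maximizing the summed explained inertia on the compositional and geographic
matrices is selected.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .chase import Partition
from .community_data import SiteMatrix
from .errors import ConfigError, DegenerateInputError, SizeError
from .similarity import geo_matrix

__all__ = [
    "WardConfig", "Dendrogram", "occupancy_distance", "mixed_dissimilarity",
    "ward_tree", "cut_tree", "explained_inertia", "select_alpha", "ward_cluster",
]


@dataclass(frozen=True)
class WardConfig:
    """alpha: mixing weight in [0,1], or "auto" for grid selection.
    alpha_grid_step must divide 1 exactly in decimal (e.g. 0.01, 0.05).
    selection: "sum" maximizes Q0+Q1 over the grid, "min" maximizes
    min(Q0, Q1). normalize: max-normalize D0/D1 before mixing (raw mixing
    available for scale-aware users)."""

    alpha: float | str = "auto"
    alpha_grid_step: float = 0.01
    k: int = 6
    selection: str = "sum"
    normalize: bool = True

    def __post_init__(self) -> None:
        if isinstance(self.alpha, str):
            if self.alpha != "auto":
                raise ConfigError("alpha must be a float in [0,1] or 'auto'")
        elif not (0.0 <= self.alpha <= 1.0):
            raise ConfigError("alpha must be in [0,1]")
        # the grid must land exactly on 1.0 in decimal
        steps = round(1.0 / self.alpha_grid_step)
        if abs(steps * self.alpha_grid_step - 1.0) > 1e-12:
            raise ConfigError("alpha_grid_step must divide 1 exactly")
        if self.k < 1:
            raise ConfigError("k must be >= 1")
        if self.selection not in ("sum", "min"):
            raise ConfigError("selection must be 'sum' or 'min'")


@dataclass
class Dendrogram:
    """Agglomeration record: merges[t] = (left, right, height) where cluster
    ids 0..n-1 are leaves and n+t is the cluster created at step t. Heights
    are non-decreasing (Ward monotonicity)."""

    n_leaves: int
    merges: list[tuple[int, int, float]]

    def __post_init__(self) -> None:
        if len(self.merges) != self.n_leaves - 1:
            raise ValueError("a dendrogram over n leaves needs n-1 merges")
        heights = [h for _, _, h in self.merges]
        if any(b < a - 1e-9 for a, b in zip(heights, heights[1:])):
            raise ValueError("Ward merge heights must be non-decreasing")

    def heights(self) -> np.ndarray:
        return np.array([h for _, _, h in self.merges])

    def leaf_order(self) -> list[int]:
        children: dict[int, tuple[int, int]] = {
            self.n_leaves + t: (l, r) for t, (l, r, _) in enumerate(self.merges)
        }
        order: list[int] = []
        stack = [self.n_leaves + len(self.merges) - 1]
        while stack:
            node = stack.pop()
            if node < self.n_leaves:
                order.append(node)
            else:
                l, r = children[node]
                stack.append(r)
                stack.append(l)
        return order

    def to_dict(self) -> dict:
        return {"n_leaves": self.n_leaves,
                "merges": [[int(l), int(r), float(h)] for l, r, h in self.merges]}


# ---------------------------------------------------------------------------
# Dissimilarities
# ---------------------------------------------------------------------------

def occupancy_distance(matrix: SiteMatrix) -> np.ndarray:
    """Euclidean distance between binary occupancy rows: sqrt(|A xor B|)."""
    return squareform(pdist(matrix.incidence.astype(float), metric="euclidean"))


def _max_normalize(D: np.ndarray) -> np.ndarray:
    off = D[~np.eye(D.shape[0], dtype=bool)]
    m = off.max() if off.size else 0.0
    if m <= 0:
        raise DegenerateInputError(
            "all dissimilarities are zero; matrix cannot be normalized")
    return D / m


def mixed_dissimilarity(D0: np.ndarray, D1: np.ndarray, alpha: float,
                        normalize: bool = True) -> np.ndarray:
    """Convex combination (1-alpha)*D0* + alpha*D1* of (optionally
    max-normalized) compositional and geographic dissimilarities."""
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must be in [0,1]")
    if D0.shape != D1.shape:
        raise ValueError("dissimilarity matrices must share a site ordering")
    if normalize:
        D0, D1 = _max_normalize(D0), _max_normalize(D1)
    return (1.0 - alpha) * D0 + alpha * D1


# ---------------------------------------------------------------------------
# Ward agglomeration (Lance-Williams), cutting, inertia
# ---------------------------------------------------------------------------

def ward_tree(D: np.ndarray) -> Dendrogram:
    """Ward linkage on a precomputed dissimilarity matrix.

    Works on squared dissimilarities with the Lance-Williams update
    d²(k, i∪j) = [(n_i+n_k)d²(k,i) + (n_j+n_k)d²(k,j) - n_k d²(i,j)]
                 / (n_i+n_j+n_k),
    merging the closest active pair at each step (ties -> lowest indices);
    merge height is sqrt of the minimized squared distance, matching the
    convention of standard Ward implementations on observation distances.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.ndim != 2 or D.shape[1] != n:
        raise ValueError("D must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("D must be symmetric")
    if n < 2:
        raise SizeError("need at least 2 leaves")

    # d2 over up to 2n-1 cluster slots; inactive slots masked with inf
    total = 2 * n - 1
    d2 = np.full((total, total), np.inf)
    d2[:n, :n] = D ** 2
    np.fill_diagonal(d2, np.inf)
    active = np.zeros(total, dtype=bool)
    active[:n] = True
    sizes = np.zeros(total, dtype=np.int64)
    sizes[:n] = 1

    merges: list[tuple[int, int, float]] = []
    for t in range(n - 1):
        idx = np.flatnonzero(active)
        sub = d2[np.ix_(idx, idx)]
        flat = int(np.argmin(sub))            # row-major -> lowest indices win ties
        i, j = idx[flat // len(idx)], idx[flat % len(idx)]
        if i > j:
            i, j = j, i
        h2 = d2[i, j]
        new = n + t
        ni, nj = sizes[i], sizes[j]
        # Lance-Williams update against every other active cluster
        others = idx[(idx != i) & (idx != j)]
        if others.size:
            no = sizes[others].astype(float)
            upd = ((no + ni) * d2[i, others] + (no + nj) * d2[j, others]
                   - no * h2) / (no + ni + nj)
            d2[new, others] = upd
            d2[others, new] = upd
        active[i] = active[j] = False
        active[new] = True
        sizes[new] = ni + nj
        merges.append((int(i), int(j), float(np.sqrt(h2))))
    return Dendrogram(n_leaves=n, merges=merges)


def cut_tree(dend: Dendrogram, k: int,
             site_ids: Optional[list[str]] = None) -> Partition:
    """Partition into exactly k clusters by undoing the k-1 highest merges."""
    n = dend.n_leaves
    if not (1 <= k <= n):
        raise SizeError(f"k must be in [1, {n}], got {k}")
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for t, (l, r, _) in enumerate(dend.merges[: n - k]):
        new = n + t
        parent[find(l)] = new
        parent[find(r)] = new
    roots = {find(i) for i in range(n)}
    root_ix = {r: c for c, r in enumerate(sorted(roots))}
    labels = np.array([root_ix[find(i)] for i in range(n)], dtype=np.int64)
    ids = site_ids if site_ids is not None else [str(i) for i in range(n)]
    return Partition.from_labels(ids, labels)


def explained_inertia(P: Partition, D: np.ndarray) -> float:
    """Q = 1 - within-cluster pseudo-inertia / total pseudo-inertia.

    Pseudo-inertia of a set from pairwise dissimilarities:
    sum_{i<j in set} D[i,j]^2 / |set|. Q = 0 at k = 1, Q = 1 at k = n.
    """
    D2 = np.asarray(D, dtype=float) ** 2
    n = D2.shape[0]
    if len(P.labels) != n:
        raise ValueError("partition does not cover D's sites")
    total = D2[np.triu_indices(n, 1)].sum() / n
    if total <= 0:
        raise DegenerateInputError("total pseudo-inertia is zero")
    within = 0.0
    for c in np.unique(P.labels):
        idx = np.flatnonzero(P.labels == c)
        if len(idx) > 1:
            sub = D2[np.ix_(idx, idx)]
            within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    return 1.0 - within / total


def select_alpha(matrix: SiteMatrix, k: int,
                 cfg: WardConfig = WardConfig()) -> tuple[float, pd.DataFrame]:
    """Scan the alpha grid; for each alpha cut the mixed-dissimilarity Ward
    tree at k and score explained inertia on the normalized compositional
    (Q0) and geographic (Q1) matrices. Returns (selected alpha, full curve);
    ties go to the smallest alpha."""
    D0 = _max_normalize(occupancy_distance(matrix))
    D1 = _max_normalize(geo_matrix(matrix).D)
    steps = round(1.0 / cfg.alpha_grid_step)
    rows = []
    best_alpha, best_score = None, -np.inf
    for s in range(steps + 1):
        alpha = s * cfg.alpha_grid_step
        D = (1.0 - alpha) * D0 + alpha * D1
        P = cut_tree(ward_tree(D), k, list(matrix.site_ids))
        q0 = explained_inertia(P, D0)
        q1 = explained_inertia(P, D1)
        rows.append({"alpha": alpha, "Q0": q0, "Q1": q1})
        score = q0 + q1 if cfg.selection == "sum" else min(q0, q1)
        if score > best_score + 1e-12:
            best_alpha, best_score = alpha, score
    return best_alpha, pd.DataFrame(rows)


def ward_cluster(matrix: SiteMatrix, cfg: WardConfig) -> tuple[Partition, float, pd.DataFrame, Dendrogram]:
    """Full pipeline: choose alpha (grid or fixed), build the mixed tree, cut
    at cfg.k. Returns (partition, alpha, alpha-curve, dendrogram); the curve
    is empty for fixed alpha."""
    if matrix.n_sites < max(2, cfg.k):
        raise SizeError("fewer sites than requested clusters")
    if cfg.alpha == "auto":
        alpha, curve = select_alpha(matrix, cfg.k, cfg)
    else:
        alpha, curve = float(cfg.alpha), pd.DataFrame(columns=["alpha", "Q0", "Q1"])
    D = mixed_dissimilarity(occupancy_distance(matrix), geo_matrix(matrix).D,
                            alpha, normalize=cfg.normalize)
    dend = ward_tree(D)
    P = cut_tree(dend, cfg.k, list(matrix.site_ids))
    return P, alpha, curve, dend
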