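"""Chase clustering: seeded, penalized, multi-start stochastic partition
optimization with endogenous cluster number.

The method clusters sites of a binary incidence matrix purely by
compositional overlap. Clusters are seeded from richness-weighted samples of
compositionally distinct sites; the remaining sites are "chased" into the
most similar seed cluster; assignments are then shuffled stochastically to
maximize a penalized coherence objective

    F(P) = sum over non-empty clusters c of
              sum over unordered site pairs {i,j} in c of (S[i,j] + gamma)
           - singleton_penalty * (# clusters with exactly one site)

where S is the pairwise similarity ("chase") matrix and gamma <= 0 is a
regularization on each within-cluster pair. More negative gamma penalizes
weakly overlapping pairs and produces more clusters; the number of non-empty
clusters (k_effective) is therefore determined by the data rather than fixed
in advance. This functional form is a documented reconstruction of the
method from its published description; a mean-per-pair alternative is
available via ``ChaseConfig.pair_form = "mean"``.

The shuffle loop runs over k_requested = k_min..k_max with ``n_starts``
independent seeded starts of ``n_shuffles`` proposal steps each, retaining
the best partition ever visited. Acceptance is greedy by default; setting
``anneal_t0 > 0`` enables a simulated-annealing acceptance rule with
geometric cooling.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy.optimize import linear_sum_assignment

from .community_data import SiteMatrix
from .errors import ConfigError, SizeError
from .similarity import ChaseMatrix, chase_matrix

_TIE_TOL = 1e-9


# ---------------------------------------------------------------------------
# Configuration and partition containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChaseConfig:
    """Tunable parameters of the chase optimizer.

    gamma: per-pair regularization in [-0.5, 0]; more negative -> more
        clusters. k_min/k_max: requested-k search range. n_starts/n_shuffles:
        multi-start breadth and per-start proposal steps. singleton_penalty:
        objective deduction per one-site cluster (larger than any plausible
        single pair term by default, so singletons survive only when every
        merge is strongly negative). anneal_t0 = 0 means greedy acceptance;
        > 0 enables annealing with temperature t0 * anneal_decay**step.
        seed_similarity_cap: maximum similarity a new seed may have to any
        already-chosen seed (relaxed in +0.1 steps when no candidate
        qualifies). pair_form: "sum" (default) or "mean" within-cluster pair
        aggregation.
    """

    gamma: float = -0.10
    k_min: int = 2
    k_max: int = 15
    n_starts: int = 250
    n_shuffles: int = 10_000
    singleton_penalty: float = 5.0
    anneal_t0: float = 0.0
    anneal_decay: float = 0.995
    seed_similarity_cap: float = 0.5
    rng_seed: int = 0
    pair_form: str = "sum"

    def __post_init__(self) -> None:
        if not (-0.5 <= self.gamma <= 0.0):
            raise ConfigError(f"gamma must be in [-0.5, 0], got {self.gamma}")
        if self.k_min < 2:
            raise ConfigError("k_min must be >= 2")
        if self.k_max < self.k_min:
            raise ConfigError("k_max must be >= k_min")
        if self.n_starts < 1 or self.n_shuffles < 1:
            raise ConfigError("n_starts and n_shuffles must be >= 1")
        if self.singleton_penalty <= 0:
            raise ConfigError("singleton_penalty must be positive")
        if self.anneal_t0 < 0:
            raise ConfigError("anneal_t0 must be >= 0")
        if not (0.0 < self.anneal_decay < 1.0):
            raise ConfigError("anneal_decay must be in (0,1)")
        if not (0.0 <= self.seed_similarity_cap <= 1.0):
            raise ConfigError("seed_similarity_cap must be in [0,1]")
        if self.rng_seed < 0:
            raise ConfigError("rng_seed must be a non-negative integer")
        if self.pair_form not in ("sum", "mean"):
            raise ConfigError("pair_form must be 'sum' or 'mean'")


def canonicalize_labels(labels: np.ndarray) -> tuple[np.ndarray, int]:
    """Relabel non-empty clusters 0..k_effective-1 by descending size, ties
    broken by the lowest member index. Returns (new labels, k_effective)."""
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    order = sorted(
        uniq,
        key=lambda c: (-int((labels == c).sum()), int(np.argmax(labels == c))),
    )
    mapping = {c: i for i, c in enumerate(order)}
    return np.array([mapping[c] for c in labels], dtype=np.int64), len(uniq)


@dataclass(frozen=True)
class Partition:
    """A complete assignment of sites to non-empty clusters.

    Labels are canonical: clusters numbered 0..k_effective-1 by descending
    size then lowest member site (site order is the lexicographic row order
    of the incidence matrix, so this is the lowest member site_id).
    """

    site_ids: tuple[str, ...]
    labels: np.ndarray
    k_effective: int
    objective: Optional[float] = None

    @classmethod
    def from_labels(
        cls,
        site_ids: Sequence[str],
        labels: np.ndarray,
        objective: Optional[float] = None,
    ) -> "Partition":
        canon, k_eff = canonicalize_labels(labels)
        return cls(site_ids=tuple(site_ids), labels=canon,
                   k_effective=k_eff, objective=objective)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"site_id": list(self.site_ids),
                             "cluster": self.labels})


@dataclass
class ChaseResult:
    """Outcome of a full chase run.

    best: globally best partition across the k sweep. per_k: one row per
    requested k (k_requested, best_objective, k_effective). runs: retained
    per-start partitions for the winning requested k. stability: per-site
    fraction of retained runs in which the site joined its reference-matched
    cluster; consistent_fraction: share of sites with stability >= 0.9.
    """

    best: Partition
    per_k: pd.DataFrame
    runs: list[Partition]
    stability: np.ndarray
    consistent_fraction: float
    config: ChaseConfig

    def assignments(self) -> pd.DataFrame:
        df = self.best.to_frame()
        df["stability"] = self.stability
        return df

    def to_dict(self) -> dict:
        return {
            "selected_k": int(self.best.k_effective),
            "objective": float(self.best.objective),
            "gamma": self.config.gamma,
            "consistent_fraction": float(self.consistent_fraction),
            "assignments": {
                s: int(c) for s, c in zip(self.best.site_ids, self.best.labels)
            },
            "stability": {
                s: float(v) for s, v in zip(self.best.site_ids, self.stability)
            },
            "per_k": self.per_k.to_dict(orient="records"),
        }


# ---------------------------------------------------------------------------
# Objective
# ---------------------------------------------------------------------------

def _cluster_contrib(pair_sum: float, m: int, gamma: float,
                     penalty: float, mean_form: bool) -> float:
    if m <= 0:
        return 0.0
    if m == 1:
        return -penalty
    npairs = 0.5 * m * (m - 1)
    if mean_form:
        return pair_sum / npairs + gamma
    return pair_sum + gamma * npairs


def _objective_labels(labels: np.ndarray, S: np.ndarray, gamma: float,
                      penalty: float, pair_form: str = "sum") -> float:
    mean_form = pair_form == "mean"
    F = 0.0
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        m = len(idx)
        sub = S[np.ix_(idx, idx)]
        pair_sum = 0.5 * (sub.sum() - np.trace(sub))
        F += _cluster_contrib(pair_sum, m, gamma, penalty, mean_form)
    return F


def objective(P: Partition, C: ChaseMatrix, gamma: float,
              singleton_penalty: float, pair_form: str = "sum") -> float:
    """Penalized coherence objective F(P); higher is better."""
    if len(P.site_ids) != C.n_sites:
        raise ValueError("partition does not cover the chase matrix's sites")
    return _objective_labels(P.labels, C.S, gamma, singleton_penalty, pair_form)


def move_delta(labels: np.ndarray, S: np.ndarray, i: int, target: int,
               gamma: float, penalty: float, pair_form: str = "sum") -> float:
    """Incremental objective change of moving site i to cluster ``target``.

    Exactly the update the shuffle kernel applies; equals
    F(after) - F(before) up to floating-point associativity.
    """
    mean_form = pair_form == "mean"
    a = labels[i]
    if target == a:
        return 0.0
    in_a = (labels == a)
    in_b = (labels == target)
    m_a, m_b = int(in_a.sum()), int(in_b.sum())
    Ti_a = float(S[i, in_a].sum())          # includes S[i,i] = 1
    Ti_b = float(S[i, in_b].sum())
    P_a = 0.5 * (S[np.ix_(in_a, in_a)].sum() - np.trace(S[np.ix_(in_a, in_a)]))
    P_b = 0.5 * (S[np.ix_(in_b, in_b)].sum() - np.trace(S[np.ix_(in_b, in_b)]))
    return (
        _cluster_contrib(P_a - (Ti_a - S[i, i]), m_a - 1, gamma, penalty, mean_form)
        + _cluster_contrib(P_b + Ti_b, m_b + 1, gamma, penalty, mean_form)
        - _cluster_contrib(P_a, m_a, gamma, penalty, mean_form)
        - _cluster_contrib(P_b, m_b, gamma, penalty, mean_form)
    )


# ---------------------------------------------------------------------------
# Numba shuffle kernel
# ---------------------------------------------------------------------------

@njit(cache=False)
def _shuffle_kernel(S, labels, k_req, gamma, penalty, mean_form,
                    site_u, targ_u, acc_u, t0, decay):  # pragma: no cover
    n = S.shape[0]
    n_shuffles = site_u.shape[0]

    T = np.zeros((n, k_req))
    sizes = np.zeros(k_req, dtype=np.int64)
    for j in range(n):
        sizes[labels[j]] += 1
    for i in range(n):
        for j in range(n):
            T[i, labels[j]] += S[i, j]
    Pc = np.zeros(k_req)
    for i in range(n):
        Pc[labels[i]] += T[i, labels[i]] - S[i, i]
    for c in range(k_req):
        Pc[c] *= 0.5

    F = 0.0
    for c in range(k_req):
        m = sizes[c]
        if m == 1:
            F -= penalty
        elif m > 1:
            npairs = 0.5 * m * (m - 1)
            if mean_form:
                F += Pc[c] / npairs + gamma
            else:
                F += Pc[c] + gamma * npairs

    best = labels.copy()
    F_best = F
    cand = np.empty(k_req, dtype=np.int64)

    for s in range(n_shuffles):
        i = int(site_u[s] * n)
        if i >= n:
            i = n - 1
        # non-empty clusters, plus (when k_effective < requested) one dormant
        ncand = 0
        dormant = -1
        for c in range(k_req):
            if sizes[c] > 0:
                cand[ncand] = c
                ncand += 1
            elif dormant < 0:
                dormant = c
        if dormant >= 0:
            cand[ncand] = dormant
            ncand += 1
        t = cand[int(targ_u[s] * ncand)] if int(targ_u[s] * ncand) < ncand \
            else cand[ncand - 1]
        a = labels[i]
        if t == a:
            continue

        m_a, m_b = sizes[a], sizes[t]
        Pa_new = Pc[a] - (T[i, a] - S[i, i])
        Pb_new = Pc[t] + T[i, t]

        dF = 0.0
        # contribution changes of cluster a
        if m_a == 1:
            dF += penalty                     # singleton disappears
        else:
            npairs = 0.5 * m_a * (m_a - 1)
            old = Pc[a] / npairs + gamma if mean_form else Pc[a] + gamma * npairs
            if m_a - 1 == 1:
                new = -penalty
            else:
                np2 = 0.5 * (m_a - 1) * (m_a - 2)
                new = Pa_new / np2 + gamma if mean_form else Pa_new + gamma * np2
            dF += new - old
        # contribution changes of cluster t
        if m_b == 0:
            dF += -penalty                    # new singleton opens
        elif m_b == 1:
            old = -penalty
            new = Pb_new + gamma          # one pair either way the form is read
            dF += new - old
        else:
            npairs = 0.5 * m_b * (m_b - 1)
            old = Pc[t] / npairs + gamma if mean_form else Pc[t] + gamma * npairs
            np2 = 0.5 * (m_b + 1) * m_b
            new = Pb_new / np2 + gamma if mean_form else Pb_new + gamma * np2
            dF += new - old

        accept = dF > 0.0
        if (not accept) and t0 > 0.0:
            temp = t0 * decay ** s
            if temp > 1e-300 and acc_u[s] < np.exp(dF / temp):
                accept = True
        if accept:
            Pc[a] = Pa_new
            Pc[t] = Pb_new
            sizes[a] -= 1
            sizes[t] += 1
            labels[i] = t
            for j in range(n):
                T[j, a] -= S[j, i]
                T[j, t] += S[j, i]
            F += dF
            if F > F_best + 1e-12:
                F_best = F
                for j in range(n):
                    best[j] = labels[j]
    return best, F_best


# ---------------------------------------------------------------------------
# Seeding and optimization
# ---------------------------------------------------------------------------

def seed_partition(C: ChaseMatrix, richness: np.ndarray, k: int,
                   rng: np.random.Generator,
                   seed_similarity_cap: float = 0.5) -> Partition:
    """Seed k clusters from richness-weighted, compositionally distinct sites
    and chase the remaining sites into the most similar seed cluster.

    Seeds are drawn sequentially with probability proportional to species
    richness; a candidate whose similarity to any already-chosen seed exceeds
    the cap is excluded, and the cap is relaxed by +0.1 when no candidate
    qualifies. Ties in the chase-in assignment go to the lowest cluster index.
    """
    n = C.n_sites
    if k > n:
        raise SizeError(f"k={k} exceeds the number of sites ({n})")
    S = C.S
    w = np.asarray(richness, dtype=float)
    if w.sum() <= 0:
        w = np.ones(n)

    seeds: list[int] = []
    cap = float(seed_similarity_cap)
    while len(seeds) < k:
        if seeds:
            max_sim = S[:, seeds].max(axis=1)
        else:
            max_sim = np.zeros(n)
        eligible = np.flatnonzero(max_sim <= cap)
        eligible = eligible[~np.isin(eligible, seeds)]
        if eligible.size == 0:
            cap += 0.1
            continue
        p = w[eligible]
        p = p / p.sum() if p.sum() > 0 else np.full(eligible.size, 1 / eligible.size)
        seeds.append(int(rng.choice(eligible, p=p)))

    labels = np.empty(n, dtype=np.int64)
    seed_arr = np.array(seeds)
    for c, s in enumerate(seeds):
        labels[s] = c
    rest = np.setdiff1d(np.arange(n), seed_arr)
    if rest.size:
        labels[rest] = np.argmax(S[np.ix_(rest, seed_arr)], axis=1)
    return Partition(site_ids=tuple(C.site_ids), labels=labels,
                     k_effective=len(np.unique(labels)))


def optimize_partition(C: ChaseMatrix, P0: Partition, cfg: ChaseConfig,
                       rng: np.random.Generator,
                       k_requested: Optional[int] = None) -> Partition:
    """Run the shuffle loop from P0, returning the best partition visited.

    Each of cfg.n_shuffles steps proposes moving a uniformly chosen site to a
    uniformly chosen target among the non-empty clusters plus, while
    k_effective < k_requested, one dormant cluster; the move is accepted when
    it improves the objective (or by the annealing rule when anneal_t0 > 0).
    The incumbent objective never decreases relative to P0.
    """
    if len(P0.site_ids) != C.n_sites:
        raise ValueError("P0 does not cover the chase matrix's sites")
    k_req = k_requested if k_requested is not None else max(P0.k_effective, 2)
    labels = P0.labels.astype(np.int64).copy()
    site_u = rng.random(cfg.n_shuffles)
    targ_u = rng.random(cfg.n_shuffles)
    acc_u = rng.random(cfg.n_shuffles)
    best, _ = _shuffle_kernel(
        np.ascontiguousarray(C.S, dtype=np.float64), labels, k_req,
        cfg.gamma, cfg.singleton_penalty, cfg.pair_form == "mean",
        site_u, targ_u, acc_u, cfg.anneal_t0, cfg.anneal_decay)
    F_best = _objective_labels(best, C.S, cfg.gamma, cfg.singleton_penalty,
                               cfg.pair_form)
    return Partition.from_labels(C.site_ids, best, objective=F_best)


# ---------------------------------------------------------------------------
# Full run and stability
# ---------------------------------------------------------------------------

def _start_rng(seed: int, k: int, start: int) -> np.random.Generator:
    # per-(k, start) independent streams: results invariant to execution order
    return np.random.default_rng(np.random.SeedSequence([seed, k, start]))


def run_chase(matrix: SiteMatrix, cfg: ChaseConfig = ChaseConfig(),
              metric: str = "jaccard") -> ChaseResult:
    """Full chase clustering over requested k = k_min..k_max.

    For each k, n_starts independent seeded starts are optimized and the best
    retained; the global best maximizes the penalized objective across all k
    (ties -> smaller k_effective, then smaller requested k). Per-site
    stability is computed over the retained runs of the winning requested k.
    Fully reproducible given cfg.rng_seed.
    """
    n = matrix.n_sites
    if n < cfg.k_min:
        raise SizeError(f"need at least k_min={cfg.k_min} sites, have {n}")
    C = chase_matrix(matrix, metric)
    richness = matrix.richness()

    per_k_rows = []
    runs_by_k: dict[int, list[Partition]] = {}
    best_by_k: dict[int, Partition] = {}
    k_hi = min(cfg.k_max, n)
    for k in range(cfg.k_min, k_hi + 1):
        best_k: Optional[Partition] = None
        runs_k: list[Partition] = []
        for start in range(cfg.n_starts):
            rng = _start_rng(cfg.rng_seed, k, start)
            P0 = seed_partition(C, richness, k, rng, cfg.seed_similarity_cap)
            P = optimize_partition(C, P0, cfg, rng, k_requested=k)
            runs_k.append(P)
            if (best_k is None or P.objective > best_k.objective + _TIE_TOL
                    or (abs(P.objective - best_k.objective) <= _TIE_TOL
                        and P.k_effective < best_k.k_effective)):
                best_k = P
        runs_by_k[k] = runs_k
        best_by_k[k] = best_k
        per_k_rows.append({"k_requested": k,
                           "best_objective": best_k.objective,
                           "k_effective": best_k.k_effective})

    best_k_req = None
    best: Optional[Partition] = None
    for k in range(cfg.k_min, k_hi + 1):
        P = best_by_k[k]
        if best is None or P.objective > best.objective + _TIE_TOL:
            best, best_k_req = P, k
        elif (abs(P.objective - best.objective) <= _TIE_TOL
              and P.k_effective < best.k_effective):
            best, best_k_req = P, k

    runs = runs_by_k[best_k_req]
    per_site, consistent = stability(runs, best)
    return ChaseResult(best=best, per_k=pd.DataFrame(per_k_rows), runs=runs,
                       stability=per_site, consistent_fraction=consistent,
                       config=cfg)


def stability(runs: Sequence[Partition], reference: Partition,
              consistency_threshold: float = 0.9) -> tuple[np.ndarray, float]:
    """Per-site co-assignment stability across repeated runs.

    Each run's clusters are matched one-to-one to the reference clusters by
    maximum overlap (optimal assignment on the contingency table); a site is
    stable in a run when it lands in the cluster matched to its reference
    cluster. Returns (per-site stability in [0,1], share of sites with
    stability >= ``consistency_threshold``).
    """
    ref_labels = reference.labels
    n = len(reference.site_ids)
    hits = np.zeros(n)
    for run in runs:
        if tuple(run.site_ids) != tuple(reference.site_ids):
            raise ValueError("run and reference cover different site sets")
        kr = run.labels.max() + 1
        kf = ref_labels.max() + 1
        counts = np.zeros((kr, kf), dtype=np.int64)
        np.add.at(counts, (run.labels, ref_labels), 1)
        rows, cols = linear_sum_assignment(-counts)
        match = {int(r): int(c) for r, c in zip(rows, cols)}
        mapped = np.array([match.get(int(c), -1) for c in run.labels])
        hits += (mapped == ref_labels)
    per_site = hits / len(runs)
    return per_site, float((per_site >= consistency_threshold).mean())
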