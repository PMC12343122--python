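"""Agreement between two partitions of the same sites.

The adjusted Rand index (ARI) is computed from the pair-counting formula on
the contingency table; it is chance-corrected, so independent random
partitions score ~0 and identical partitions score 1. The classical formula
is undefined when its denominator vanishes (both partitions trivial); here
that degenerate case returns 1 when the partitions are equal and 0 otherwise.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chase import Partition


@dataclass
class ContingencyTable:
    counts: np.ndarray          # n_ij: sites in cluster i of A and j of B
    row_sums: np.ndarray        # a_i
    col_sums: np.ndarray        # b_j
    n: int


def _align(A: Partition, B: Partition) -> tuple[np.ndarray, np.ndarray]:
    sa, sb = set(A.site_ids), set(B.site_ids)
    if sa != sb:
        diff = sorted(sa.symmetric_difference(sb))
        raise ValueError(
            "partitions cover different site sets; symmetric difference: "
            + ", ".join(diff))
    pos_b = {s: i for i, s in enumerate(B.site_ids)}
    order = [pos_b[s] for s in A.site_ids]
    return A.labels, B.labels[order]


def contingency(A: Partition, B: Partition) -> ContingencyTable:
    """Exact cross-tabulation of cluster memberships (B aligned to A's site order)."""
    la, lb = _align(A, B)
    counts = np.zeros((la.max() + 1, lb.max() + 1), dtype=np.int64)
    np.add.at(counts, (la, lb), 1)
    return ContingencyTable(counts=counts,
                            row_sums=counts.sum(axis=1),
                            col_sums=counts.sum(axis=0),
                            n=int(counts.sum()))


def _comb2(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x * (x - 1) / 2.0


def adjusted_rand_index(A: Partition, B: Partition) -> float:
    """Pair-counting ARI; 1 for identical partitions, ~0 for independent ones."""
    ct = contingency(A, B)
    sum_ij = _comb2(ct.counts).sum()
    sum_a = _comb2(ct.row_sums).sum()
    sum_b = _comb2(ct.col_sums).sum()
    pairs = _comb2(np.array([ct.n]))[0]
    expected = sum_a * sum_b / pairs if pairs > 0 else 0.0
    denom = 0.5 * (sum_a + sum_b) - expected
    if denom == 0:
        la, lb = _align(A, B)
        # equality as set partitions: canonicalize by order of first occurrence
        def first_occurrence(l):
            _, idx = np.unique(l, return_index=True)
            rank = {l[i]: r for r, i in enumerate(sorted(idx))}
            return np.array([rank[x] for x in l])
        return 1.0 if np.array_equal(first_occurrence(la),
                                     first_occurrence(lb)) else 0.0
    return float((sum_ij - expected) / denom)


def comparison_report(A: Partition, B: Partition) -> dict:
    """ARI, contingency table, and each A-cluster's best-matching B-cluster."""
    ct = contingency(A, B)
    best = {
        int(i): {"b_cluster": int(np.argmax(row)),
                 "overlap": int(row.max()),
                 "size": int(ct.row_sums[i])}
        for i, row in enumerate(ct.counts)
    }
    return {
        "ari": adjusted_rand_index(A, B),
        "n_sites": ct.n,
        "contingency": ct.counts.tolist(),
        "best_matches": best,
    }
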