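"""Independent reference implementations used as oracles by the tests.

These deliberately re-derive results through different algorithms than the
package (full-matrix DP instead of Biopython/banded kernels, one-candidate-
at-a-time tiling instead of the scanning matcher, direct Lance–Williams
agglomeration instead of scipy linkage), so agreement is meaningful.
"""

from __future__ import annotations

from typing import List, Sequence, Tuple

import numpy as np


def nw_score(
    a: str,
    b: str,
    match: int = 5,
    mismatch: int = -4,
    gap: int = -4,
    never_match: str = "?",
) -> int:
    """Plain full-matrix global alignment DP (small inputs only)."""
    n, m = len(a), len(b)
    prev = [gap * j for j in range(m + 1)]
    for i in range(1, n + 1):
        cur = [gap * i] + [0] * m
        for j in range(1, m + 1):
            s = match if (a[i - 1] == b[j - 1] and a[i - 1] not in never_match) else mismatch
            cur[j] = max(prev[j - 1] + s, prev[j] + gap, cur[j - 1] + gap)
        prev = cur
    return prev[m]


def oracle_tiling(seq: str, rs) -> List[Tuple[int, int, str]]:
    """One-candidate-at-a-time greedy tiling with full rescan per step.

    Priority: longest repeat first, then repeat-table order, then leftmost
    position. Returns (start, end, sequence) triples sorted by position.
    """
    order = sorted(enumerate(rs.repeats), key=lambda t: (-len(t[1].sequence), t[0]))
    free = [True] * len(seq)
    placed: List[Tuple[int, int, str]] = []
    while True:
        chosen = None
        for _, rep in order:
            motif = rep.sequence
            L = len(motif)
            for pos in range(len(seq) - L + 1):
                if seq[pos : pos + L] == motif and all(free[pos : pos + L]):
                    chosen = (pos, pos + L, motif)
                    break
            if chosen:
                break
        if chosen is None:
            break
        s, e, _ = chosen
        for i in range(s, e):
            free[i] = False
        placed.append(chosen)
    return sorted(placed)


def naive_ward_partition(D: np.ndarray, cut: float) -> List[List[int]]:
    """Direct Lance–Williams Ward agglomeration, merging while the merge
    height is <= cut. Ties broken by lowest cluster indices."""
    n = D.shape[0]
    clusters = {i: [i] for i in range(n)}
    d2 = {}
    for i in range(n):
        for j in range(i + 1, n):
            d2[(i, j)] = float(D[i, j]) ** 2
    next_id = n
    while len(clusters) > 1:
        best = None
        for (i, j), v in sorted(d2.items()):
            if best is None or v < best[0] - 1e-12:
                best = (v, i, j)
        v, i, j = best
        if np.sqrt(max(v, 0.0)) > cut:
            break
        ni, nj = len(clusters[i]), len(clusters[j])
        merged = sorted(clusters[i] + clusters[j])
        others = [k for k in clusters if k not in (i, j)]
        new_d2 = {}
        for k in others:
            nk = len(clusters[k])
            dik = d2[(min(i, k), max(i, k))]
            djk = d2[(min(j, k), max(j, k))]
            dij = d2[(i, j)]
            new_d2[k] = ((ni + nk) * dik + (nj + nk) * djk - nk * dij) / (ni + nj + nk)
        del clusters[i], clusters[j]
        d2 = {
            (a, b): val
            for (a, b), val in d2.items()
            if a not in (i, j) and b not in (i, j)
        }
        clusters[next_id] = merged
        for k, val in new_d2.items():
            d2[(min(k, next_id), max(k, next_id))] = val
        next_id += 1
    return sorted(clusters.values())


def partition_key(groups: Sequence[Sequence[int]]) -> frozenset:
    return frozenset(frozenset(g) for g in groups)


def symbol_identity(pattern: str, consensus: str) -> float:
    """Fraction of a truth pattern recovered in a consensus, via the best
    infix (substring) alignment; edlib provides the independent engine."""
    import edlib

    if not pattern:
        return 1.0
    res = edlib.align(pattern, consensus, mode="HW", task="distance")
    return max(0.0, 1.0 - res["editDistance"] / len(pattern))
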