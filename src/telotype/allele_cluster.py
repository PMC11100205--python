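"""Clustering of telomere reads into alleles by TVR similarity.

Reads from the same telomere allele share the same inherited pattern of
variant repeats, so pairwise alignment of their symbol strings separates
alleles cleanly. Similarity scores are converted to normalized distances
(as in progressive MSA guide-tree construction) and clustered with Ward
linkage; the dendrogram is cut at a fixed height. Each preliminary cluster
is then refined: an aggressive TVR re-clustering splits alleles that share
a long common prefix, and a subtelomere comparison splits alleles whose
TVRs are near-identical but whose flanking subtelomeres clearly differ.
Clusters whose TVR carries too few variant repeats to be distinctive are
flagged "blank" and are grouped by subtelomere sequence instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .alignment import ScoringParams, pairwise_symbol_score, symbol_aligner
from .repeat_model import RepeatSet
from .telomere_scan import TelomereRead
from .tvr_encode import SymbolString

__all__ = [
    "ScoringParams",
    "AlleleCluster",
    "pairwise_score",
    "pairwise_score_matrix",
    "score_to_distance",
    "cluster_reads",
    "refine_cluster",
    "flag_blank",
]

logger = logging.getLogger(__name__)

#: Symbols compared per read: the TVR-proximal window. Distances must
#: reflect TVR pattern, not telomere length, so strings are truncated.
DEFAULT_MAX_TVR_SYMBOLS = 500


@dataclass
class AlleleCluster:
    """A refined set of reads attributed to one telomere allele."""

    cluster_id: str
    members: List[Tuple[TelomereRead, SymbolString]]
    blank: bool = False
    consensus: Optional[SymbolString] = None
    tvr: Optional[object] = None  # ConsensusTVR, filled by consensus stage
    atl: Optional[object] = None  # ATLDistribution, filled by consensus stage
    anchor: Optional[object] = None  # AnchorResult, filled by anchoring stage

    @property
    def read_count(self) -> int:
        return len(self.members)


def pairwise_score(
    a: SymbolString | str,
    b: SymbolString | str,
    rs: RepeatSet,
    params: ScoringParams | None = None,
) -> float:
    """Optimal global alignment score between two symbol strings."""
    params = params or ScoringParams()
    aligner = symbol_aligner(rs, params)
    sa = a.symbols if isinstance(a, SymbolString) else a
    sb = b.symbols if isinstance(b, SymbolString) else b
    return pairwise_symbol_score(sa, sb, aligner, params.gap)


def pairwise_score_matrix(
    strings: Sequence[str],
    rs: RepeatSet,
    params: ScoringParams | None = None,
    max_symbols: int = DEFAULT_MAX_TVR_SYMBOLS,
    band: int | None = 48,
) -> np.ndarray:
    """Symmetric matrix of alignment scores over truncated symbol strings.

    Each pair is compared over its common prefix length (capped at
    ``max_symbols``): both strings start at the subtelomere junction, so
    pattern differences appear as mismatches within the shared window
    while telomere-length differences — which say nothing about allele
    identity — contribute no end-gap penalty.

    ``band`` restricts the alignment path to a diagonal band (see
    :mod:`telotype._banded`); within-band pairs — in particular reads of
    the same allele — score exactly. ``band=None`` runs the unrestricted
    reference DP.
    """
    params = params or ScoringParams()
    trunc = [s[:max_symbols] for s in strings]
    if band is not None:
        from ._banded import banded_score_matrix

        return banded_score_matrix(
            trunc,
            rs.alphabet,
            match=params.match,
            mismatch=params.mismatch,
            gap=params.gap,
            band=band,
            pair_truncate=True,
            nomatch=rs.unknown_symbol,
        )
    aligner = symbol_aligner(rs, params)
    n = len(trunc)
    S = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            L = min(len(trunc[i]), len(trunc[j]))
            S[i, j] = S[j, i] = pairwise_symbol_score(
                trunc[i][:L], trunc[j][:L], aligner, params.gap
            )
    return S


def score_to_distance(scores: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Normalized distances d(a,b) = 1 - S(a,b)/min(S(a,a), S(b,b)).

    The same normalization used when building guide trees for progressive
    MSA. Values are clipped to [0, 1]. Entries with non-positive
    self-score (degenerate, effectively unalignable strings) cannot be
    normalized; the returned boolean mask marks the valid rows, and the
    distance matrix covers only those.
    """
    diag = np.diag(scores).copy()
    valid = diag > 0
    if not valid.all():
        logger.info("excluding %d reads with non-positive self-score", int((~valid).sum()))
    S = scores[np.ix_(valid, valid)]
    d = np.diag(S).copy()
    denom = np.minimum.outer(d, d)
    D = 1.0 - S / denom
    np.clip(D, 0.0, 1.0, out=D)
    np.fill_diagonal(D, 0.0)
    return D, valid


def cluster_reads(
    dist: np.ndarray,
    cut: float = 0.40,
    min_reads: int = 3,
) -> Tuple[List[List[int]], List[int]]:
    """Ward-linkage hierarchical clustering cut at a fixed height.

    Returns (clusters, unassigned): clusters are lists of row indices with
    at least ``min_reads`` members, deterministic in content and order;
    smaller groups land in ``unassigned``.
    """
    n = dist.shape[0]
    if n == 0:
        return [], []
    if n == 1:
        return ([[0]], []) if min_reads <= 1 else ([], [0])
    Z = linkage(squareform(dist, checks=False), method="ward")
    labels = fcluster(Z, t=cut, criterion="distance")
    groups: dict[int, list[int]] = {}
    for idx, lab in enumerate(labels):
        groups.setdefault(int(lab), []).append(idx)
    clusters = [sorted(v) for v in groups.values()]
    clusters.sort(key=lambda c: (-len(c), c[0]))
    kept = [c for c in clusters if len(c) >= min_reads]
    unassigned = sorted(i for c in clusters if len(c) < min_reads for i in c)
    return kept, unassigned


def subtelomere_distance_matrix(
    members: Sequence[TelomereRead],
    params: ScoringParams | None = None,
    compare_bp: int = 1000,
) -> np.ndarray:
    """Normalized distances between members' telomere-proximal subtelomere.

    Only the ``compare_bp`` bases adjacent to the telomere are compared:
    they are always present on every retained read and carry the
    arm-distinguishing signal.
    """
    from ._banded import banded_score_matrix

    params = params or ScoringParams()
    seqs = [m.subtel_seq[-compare_bp:] for m in members]
    S = banded_score_matrix(
        seqs,
        "ACGT",
        match=params.match,
        mismatch=params.mismatch,
        gap=params.gap,
        band=64,
        pair_truncate=False,
        nomatch="N",
    )
    D, valid = score_to_distance(S)
    if not valid.all():  # all-N subtelomere; treat as maximally distant
        full = np.ones((n, n))
        np.fill_diagonal(full, 0.0)
        full[np.ix_(valid, valid)] = D
        return full
    return D


def refine_cluster(
    members: List[Tuple[TelomereRead, SymbolString]],
    rs: RepeatSet,
    aggressive_cut: float = 0.25,
    subtel_cut: float = 0.25,
    min_reads: int = 3,
    params: ScoringParams | None = None,
    max_symbols: int = DEFAULT_MAX_TVR_SYMBOLS,
    subtel_compare_bp: int = 1000,
    scores: Optional[np.ndarray] = None,
) -> Tuple[List[List[Tuple[TelomereRead, SymbolString]]], List[Tuple[TelomereRead, SymbolString]]]:
    """Split a preliminary cluster into alleles.

    Pass 1 re-clusters member TVR symbol strings at a lower (more
    aggressive) cut, separating alleles whose patterns share a prefix.
    Pass 2 re-clusters each result by subtelomere sequence, separating
    alleles with near-identical TVRs but divergent flanks. Returns
    (refined clusters, unassigned members).

    ``scores`` may carry the members' precomputed pairwise score matrix
    (the comparison scheme is identical to the preliminary stage).
    """
    params = params or ScoringParams()
    unassigned: List[Tuple[TelomereRead, SymbolString]] = []

    def _split_tvr(group):
        if scores is not None:
            S = scores
        else:
            strings = [ss.symbols for _, ss in group]
            S = pairwise_score_matrix(strings, rs, params, max_symbols)
        D, valid = score_to_distance(S)
        kept_items = [g for g, v in zip(group, valid) if v]
        unassigned.extend(g for g, v in zip(group, valid) if not v)
        clusters, un = cluster_reads(D, cut=aggressive_cut, min_reads=min_reads)
        unassigned.extend(kept_items[i] for i in un)
        return [[kept_items[i] for i in c] for c in clusters]

    def _split_subtel(group):
        reads = [r for r, _ in group]
        D = subtelomere_distance_matrix(reads, params, compare_bp=subtel_compare_bp)
        clusters, un = cluster_reads(D, cut=subtel_cut, min_reads=min_reads)
        unassigned.extend(group[i] for i in un)
        return [[group[i] for i in c] for c in clusters]

    refined: List[List[Tuple[TelomereRead, SymbolString]]] = []
    for tvr_group in _split_tvr(members):
        refined.extend(_split_subtel(tvr_group))
    return refined, unassigned


def flag_blank(cluster: AlleleCluster, rs: RepeatSet, min_variants: int = 5) -> AlleleCluster:
    """Mark a cluster blank when its TVR carries too few variant repeats.

    Blank means the median per-member variant-repeat count is strictly
    below ``min_variants``; such clusters cannot be told apart by TVR
    pattern and are grouped by subtelomere sequence downstream.
    """
    counts = [ss.variant_count(rs) for _, ss in cluster.members]
    cluster.blank = bool(np.median(counts) < min_variants) if counts else True
    return cluster
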