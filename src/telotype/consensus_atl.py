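"""Per-allele consensus TVR, TVR boundary, and telomere-length distribution.

For each refined cluster a consensus symbol string is built by progressive
multiple alignment of the member symbol strings. The scoring matrix scores
any symbol match +5 except canonical-canonical, which scores 0: alignment
is then driven by the variant-repeat blocks rather than by the long runs
of canonical repeats between them, and sequencing errors in individual
reads vote themselves out of the consensus.

The TVR boundary is the position by which 95% of the cumulative variant
repeats in the consensus have been seen — the most distal variant repeat,
tempered against sporadic error-induced variants deep in the telomere.
Each supporting read's telomere length (ATL) is then how far the read
extends beyond that boundary, mapped onto the read through its alignment
to the consensus; the cluster reports the whole length distribution plus a
representative value (75th percentile by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .alignment import ScoringParams, symbol_aligner
from .repeat_model import RepeatSet
from .tvr_encode import SymbolString, prune_singletons

__all__ = [
    "ConsensusTVR",
    "ATLDistribution",
    "msa_consensus",
    "tvr_boundary",
    "atl_distribution",
    "representative_atl",
]

logger = logging.getLogger(__name__)


@dataclass
class ConsensusTVR:
    """Consensus symbols with the TVR/telomere boundary.

    ``tvr_boundary_symbol`` is the exclusive end of the TVR region in
    symbol coordinates (``symbols.symbols[:tvr_boundary_symbol]`` is TVR);
    ``tvr_boundary_bp`` is the corresponding base offset. ``support`` is
    the per-column read depth of the consensus.
    """

    symbols: SymbolString
    tvr_boundary_symbol: int
    tvr_boundary_bp: int
    support: Optional[np.ndarray] = None


@dataclass
class ATLDistribution:
    """Per-read telomere lengths beyond the TVR boundary, with a summary."""

    lengths_bp: List[int]
    method: str
    representative_bp: float


def _column_majority(column: List[str], rs: RepeatSet) -> str:
    """Majority symbol in an alignment column, ties broken toward canonical,
    then by symbol-table order for determinism."""
    counts: dict[str, int] = {}
    for s in column:
        counts[s] = counts.get(s, 0) + 1
    best = max(counts.values())
    tied = [s for s, c in counts.items() if c == best]
    if rs.canonical_symbol in tied:
        return rs.canonical_symbol
    order = rs.alphabet
    tied.sort(key=lambda s: order.index(s) if s in order else len(order))
    return tied[0]


def _medoid_order(strings: Sequence[str], rs: RepeatSet, params: ScoringParams) -> List[int]:
    """Members ordered for progressive alignment: medoid first, then by
    decreasing similarity to the medoid."""
    n = len(strings)
    if n <= 2:
        return list(range(n))
    aligner = symbol_aligner(rs, params)
    S = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if strings[i] and strings[j]:
                S[i, j] = S[j, i] = float(aligner.score(strings[i], strings[j]))
            else:
                S[i, j] = S[j, i] = params.gap * (len(strings[i]) + len(strings[j]))
    medoid = int(np.argmax(S.sum(axis=1)))
    rest = sorted((i for i in range(n) if i != medoid), key=lambda i: (-S[medoid, i], i))
    return [medoid] + rest


def msa_consensus(
    members: Sequence[SymbolString | str],
    rs: RepeatSet,
    params: ScoringParams | None = None,
    max_symbols: int = 500,
    return_support: bool = False,
):
    """Center-star multiple alignment of symbol strings → consensus.

    The medoid member (highest summed similarity) is the star center;
    every other member is aligned to it under the canonical-match-0
    matrix and the pairwise alignments are merged on medoid coordinates,
    pooling insertions that fall in the same inter-column slot. The
    consensus is the per-column majority symbol, with ties broken toward
    canonical; columns where gaps hold the majority — member-specific
    insertions, or distal columns most members do not reach — are dropped.
    """
    if not members:
        raise ValueError("msa_consensus requires at least one member")
    params = params or ScoringParams()
    strings = [
        (m.symbols if isinstance(m, SymbolString) else m)[:max_symbols] for m in members
    ]
    order = _medoid_order(strings, rs, params)
    # plain global alignment: with canonical matches worth 0, free end gaps
    # would make truncation after the last variant co-optimal and shed the
    # canonical tail; end-gap penalties keep the full columns populated
    aligner = symbol_aligner(
        rs, params, canonical_match=params.canonical_match_consensus, gap_tiebreak=0.01
    )
    center = strings[order[0]]
    L = len(center)
    n_rows = len(strings)
    # match_cols[p][r]: member r's symbol aligned to center position p;
    # inserts[p][r]: member r's symbols inserted in the slot before p
    match_cols: List[List[str]] = [["-"] * n_rows for _ in range(L)]
    inserts: List[dict] = [dict() for _ in range(L + 1)]
    for p in range(L):
        match_cols[p][order[0]] = center[p]
    for idx in order[1:]:
        new = strings[idx]
        if not new or not center:
            continue
        aln = aligner.align(center, new)[0]
        tgt_idx, qry_idx = aln.indices  # -1 marks a gap in that sequence
        next_t = 0
        for t, q in zip(tgt_idx, qry_idx):
            if t < 0:
                inserts[next_t].setdefault(idx, []).append(new[q])
            else:
                next_t = int(t) + 1
                if q >= 0:
                    match_cols[int(t)][idx] = new[int(q)]

    rows: List[List[str]] = [[] for _ in range(n_rows)]
    for p in range(L + 1):
        ins_len = max((len(v) for v in inserts[p].values()), default=0)
        for k in range(ins_len):
            for r in range(n_rows):
                syms = inserts[p].get(r, [])
                rows[r].append(syms[k] if k < len(syms) else "-")
        if p < L:
            for r in range(n_rows):
                rows[r].append(match_cols[p][r])
    symbols: List[str] = []
    support: List[int] = []
    for c in range(len(rows[0])):
        column = [r[c] for r in rows]
        non_gap = [s for s in column if s != "-"]
        if len(non_gap) * 2 <= n_rows and n_rows > 1:
            continue  # gap-majority column
        symbols.append(_column_majority(non_gap, rs))
        support.append(len(non_gap))

    offsets: List[Tuple[int, int]] = []
    pos = 0
    for s in symbols:
        w = len(rs.decode_symbol(s))
        offsets.append((pos, pos + w))
        pos += w
    # isolated indel-variant symbols surviving the vote are still most
    # plausibly errors; apply the same singleton pruning as at read level
    consensus = prune_singletons(SymbolString("".join(symbols), offsets), rs)
    if return_support:
        return consensus, np.array(support)
    return consensus


def tvr_boundary(
    consensus: SymbolString,
    rs: RepeatSet,
    q: float = 0.95,
    support: Optional[np.ndarray] = None,
) -> ConsensusTVR:
    """Locate the TVR/telomere boundary on a consensus symbol string.

    With V total variant symbols, the boundary is placed immediately after
    the smallest prefix containing at least q*V of them, so that sporadic
    error-like variants deep in the telomere do not stretch the TVR.
    A consensus without variants ("blank" TVR) has boundary 0.
    """
    canon, unk = rs.canonical_symbol, rs.unknown_symbol
    is_var = [s not in (canon, unk) for s in consensus.symbols]
    V = sum(is_var)
    if V == 0:
        return ConsensusTVR(consensus, 0, 0, support)
    need = q * V
    count = 0
    for i, v in enumerate(is_var):
        count += v
        if count >= need:
            return ConsensusTVR(consensus, i + 1, consensus.base_offsets[i][1], support)
    return ConsensusTVR(
        consensus, len(consensus), consensus.base_offsets[-1][1], support
    )


def map_boundary_to_member(
    member: SymbolString,
    consensus: SymbolString,
    rs: RepeatSet,
    boundary_symbol: int,
    params: ScoringParams | None = None,
) -> int:
    """Member-coordinate bp offset of the consensus TVR boundary.

    The member is aligned to the consensus and the boundary column is
    projected through the alignment, so indels in the member do not bias
    its telomere length. The member (which usually extends much further
    into the telomere than the truncated consensus) is compared over a
    window slightly longer than the consensus; the excess would otherwise
    only buy end gaps.
    """
    if boundary_symbol <= 0:
        return 0
    params = params or ScoringParams()
    if not member.symbols:
        return 0
    aligner = symbol_aligner(
        rs, params, canonical_match=params.canonical_match_consensus, gap_tiebreak=0.01
    )
    window = member.symbols[: len(consensus.symbols) + 20]
    aln = aligner.align(consensus.symbols, window)[0]
    tgt_idx, qry_idx = aln.indices
    last_q = -1
    for t, q_i in zip(tgt_idx, qry_idx):
        if q_i >= 0 and 0 <= t < boundary_symbol:
            last_q = int(q_i)
        if t >= boundary_symbol:
            break
    if last_q < 0:
        return 0
    return member.base_offsets[last_q][1]


def atl_distribution(
    members: Sequence[SymbolString],
    consensus_tvr: ConsensusTVR,
    rs: RepeatSet,
    method: str = "p75",
    params: ScoringParams | None = None,
) -> ATLDistribution:
    """Telomere length beyond the TVR boundary for every supporting read."""
    if not members:
        raise ValueError("atl_distribution requires a non-empty cluster")
    lengths: List[int] = []
    for m in members:
        b = map_boundary_to_member(
            m, consensus_tvr.symbols, rs, consensus_tvr.tvr_boundary_symbol, params
        )
        atl = m.total_bp - b
        if atl < 0:
            logger.warning("negative ATL (%d) clamped to 0", atl)
            atl = 0
        lengths.append(int(atl))
    return ATLDistribution(lengths, method, representative_atl(lengths, method))


def representative_atl(lengths_bp: Sequence[float], method: str = "p75") -> float:
    """Summarize an ATL distribution: mean, median, max, or pN percentile
    (linear interpolation)."""
    arr = np.asarray(lengths_bp, dtype=float)
    if arr.size == 0:
        raise ValueError("empty ATL distribution")
    if method == "mean":
        return float(arr.mean())
    if method == "median":
        return float(np.median(arr))
    if method == "max":
        return float(arr.max())
    if method.startswith("p"):
        try:
            pct = float(method[1:])
        except ValueError:
            raise ValueError(f"unknown representative method {method!r}") from None
        if not 0 <= pct <= 100:
            raise ValueError(f"percentile out of range in {method!r}")
        return float(np.percentile(arr, pct))
    raise ValueError(f"unknown representative method {method!r}")
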