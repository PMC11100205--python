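"""Symbol-string encoding of telomere regions.

The telomere+TVR region of each read is tiled with exact matches to the
repeat set — longest repeats first, so that e.g. a TTAGGGG septamer is not
shadowed by its TTAGGG prefix — and converted to one symbol per matched
repeat. Unmatched runs become unknown symbols, one per 6bp (the canonical
repeat period), so unknown stretches stay commensurate with repeat symbols
during alignment. Isolated matches to homopolymer-indel variants of the
canonical repeat, flanked by canonical repeats, are relabeled canonical:
they are overwhelmingly sequencing errors rather than real variant repeats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Sequence, Tuple

from .repeat_model import RepeatDef, RepeatSet

__all__ = ["RepeatMatch", "SymbolString", "match_repeats", "symbolize", "prune_singletons"]


@dataclass(frozen=True)
class RepeatMatch:
    """An exact repeat occurrence claiming ``seq[start:end]``."""

    start: int
    end: int
    repeat: RepeatDef


@dataclass
class SymbolString:
    """Repeat-symbol representation of one telomere region.

    ``symbols[i]`` covers bases ``base_offsets[i] = (start, end)``; the
    intervals are sorted, non-overlapping and tile the region exactly.
    """

    symbols: str
    base_offsets: List[Tuple[int, int]]

    def __post_init__(self) -> None:
        if len(self.symbols) != len(self.base_offsets):
            raise ValueError("symbols and base_offsets length mismatch")

    def variant_count(self, rs: RepeatSet) -> int:
        canon = rs.canonical_symbol
        unk = rs.unknown_symbol
        return sum(1 for s in self.symbols if s not in (canon, unk))

    @property
    def total_bp(self) -> int:
        return self.base_offsets[-1][1] if self.base_offsets else 0

    def __len__(self) -> int:
        return len(self.symbols)


def _priority_order(rs: RepeatSet) -> list[RepeatDef]:
    """Repeats in matching priority: length descending, then table order."""
    indexed = list(enumerate(rs.repeats))
    indexed.sort(key=lambda t: (-len(t[1].sequence), t[0]))
    return [r for _, r in indexed]


def match_repeats(seq: str, rs: RepeatSet) -> List[RepeatMatch]:
    """Greedy longest-first exact tiling of ``seq`` with the repeat set.

    Repeats are matched in descending length (table order breaks ties),
    scanning left to right; an occurrence is accepted only if none of its
    positions is already claimed by an earlier (longer or higher-priority)
    match. A shorter repeat partially overlapping an accepted match is
    thereby trimmed away; its non-overlapping remnant is claimed only if
    the remnant itself equals some repeat in the set, in which case that
    repeat's own scan finds it.
    """
    seq = seq.upper()
    n = len(seq)
    claimed = bytearray(n)
    matches: List[RepeatMatch] = []
    for repeat in _priority_order(rs):
        motif = repeat.sequence
        m = len(motif)
        start = 0
        while True:
            idx = seq.find(motif, start)
            if idx < 0:
                break
            if any(claimed[idx : idx + m]):
                start = idx + 1
                continue
            claimed[idx : idx + m] = b"\x01" * m
            matches.append(RepeatMatch(idx, idx + m, repeat))
            start = idx + m
    matches.sort(key=lambda mt: mt.start)
    return matches


def symbolize(seq: str, matches: Sequence[RepeatMatch], rs: RepeatSet) -> SymbolString:
    """Convert resolved matches into a symbol string tiling the region.

    Maximal unmatched runs are encoded as ceil(run/6) unknown symbols, each
    recording the base interval it stands for.
    """
    symbols: list[str] = []
    offsets: list[Tuple[int, int]] = []
    pos = 0

    def emit_unknown(start: int, end: int) -> None:
        run = end - start
        n_sym = math.ceil(run / 6)
        chunk = start
        for i in range(n_sym):
            nxt = min(chunk + 6, end) if i < n_sym - 1 else end
            symbols.append(rs.unknown_symbol)
            offsets.append((chunk, nxt))
            chunk = nxt

    for mt in matches:
        if mt.start < pos:
            raise ValueError("overlapping matches passed to symbolize")
        if mt.start > pos:
            emit_unknown(pos, mt.start)
        symbols.append(mt.repeat.symbol)
        offsets.append((mt.start, mt.end))
        pos = mt.end
    if pos < len(seq):
        emit_unknown(pos, len(seq))
    return SymbolString("".join(symbols), offsets)


def prune_singletons(s: SymbolString, rs: RepeatSet) -> SymbolString:
    """Relabel isolated homopolymer-indel variants as canonical.

    A single symbol whose repeat is a canonical-indel variant, flanked on
    both sides by canonical symbols, is treated as a sequencing error and
    relabeled canonical (base interval unchanged). Runs of two or more are
    kept, as are substitution-type variants. Applied to a fixed point;
    idempotent.
    """
    canon = rs.canonical_symbol
    symbols = list(s.symbols)
    changed = True
    while changed:
        changed = False
        for i in range(1, len(symbols) - 1):
            sym = symbols[i]
            if sym == canon or not rs.is_indel_variant(sym):
                continue
            if symbols[i - 1] == canon and symbols[i + 1] == canon:
                symbols[i] = canon
                changed = True
    return SymbolString("".join(symbols), list(s.base_offsets))


def encode_tel_region(seq: str, rs: RepeatSet, prune: bool = True) -> SymbolString:
    """match → symbolize → (optionally) prune, as one step."""
    s = symbolize(seq, match_repeats(seq, rs), rs)
    return prune_singletons(s, rs) if prune else s
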