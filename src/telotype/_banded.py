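"""Banded global-alignment scoring kernels (numba).

All-pairs comparison dominates the pipeline's runtime. The strings being
compared share a left anchor (the subtelomere junction) and, for reads of
the same allele, differ only by scattered errors, so their optimal global
alignment stays within a narrow diagonal band. These kernels compute the
global alignment score with the path restricted to |i - j| <= band; in
that regime the result equals the unrestricted score. A pair whose
optimal path would leave the band (a large net indel shift, plausible
only between different alleles) is scored conservatively low, which can
only push an already large distance larger.

Symbols are uint8 codes; code 255 is the never-matching "unknown" class
(it scores as a mismatch even against itself).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["encode_string", "encode_matrix", "banded_global_score", "banded_score_matrix"]

_NEG = -1.0e9
NOMATCH = 255


@njit(cache=True)
def _nw_banded(a, b, la, lb, match, mismatch, gap, band):  # pragma: no cover
    if la == 0 or lb == 0:
        return gap * (la + lb)
    if band < (la - lb if la > lb else lb - la) + 8:
        band = (la - lb if la > lb else lb - la) + 8
    width = 2 * band + 1
    # rows padded by one sentinel cell on each side: index k+1 for k=j-i+band
    prev = np.full(width + 2, _NEG)
    cur = np.full(width + 2, _NEG)
    prev[band + 1] = 0.0
    for j in range(1, band + 1):
        if j > lb:
            break
        prev[band + 1 + j] = gap * j
    for i in range(1, la + 1):
        for k in range(width + 2):
            cur[k] = _NEG
        lo = i - band
        if lo < 0:
            lo = 0
        hi = i + band
        if hi > lb:
            hi = lb
        ai = a[i - 1]
        for j in range(lo, hi + 1):
            k = j - i + band + 1
            if j == 0:
                cur[k] = gap * i
                continue
            d = prev[k]
            bj = b[j - 1]
            if ai == bj and ai != NOMATCH:
                d += match
            else:
                d += mismatch
            u = prev[k + 1] + gap
            l = cur[k - 1] + gap
            best = d
            if u > best:
                best = u
            if l > best:
                best = l
            cur[k] = best
        tmp = prev
        prev = cur
        cur = tmp
    return prev[lb - la + band + 1]


@njit(cache=True)
def _self_score(a, la, match, mismatch):  # pragma: no cover
    # optimal self-alignment is the diagonal: matches everywhere except
    # unknown symbols, which mismatch against themselves (-4 beats two gaps)
    s = 0.0
    for i in range(la):
        if a[i] == NOMATCH:
            s += mismatch
        else:
            s += match
    return s


@njit(cache=True)
def _score_matrix(codes, lengths, match, mismatch, gap, band, pair_truncate):  # pragma: no cover
    n = codes.shape[0]
    S = np.zeros((n, n))
    for i in range(n):
        S[i, i] = _self_score(codes[i], lengths[i], match, mismatch)
    for i in range(n):
        for j in range(i + 1, n):
            li, lj = lengths[i], lengths[j]
            if pair_truncate:
                L = li if li < lj else lj
                s = _nw_banded(codes[i], codes[j], L, L, match, mismatch, gap, band)
            else:
                s = _nw_banded(codes[i], codes[j], li, lj, match, mismatch, gap, band)
            S[i, j] = s
            S[j, i] = s
    return S


def encode_string(s: str, alphabet: str, nomatch: str = "?") -> np.ndarray:
    """Map a string to uint8 codes; never-matching characters map to 255."""
    lut = {c: i for i, c in enumerate(alphabet)}
    out = np.empty(len(s), dtype=np.uint8)
    for i, c in enumerate(s):
        out[i] = NOMATCH if c == nomatch else lut.get(c, NOMATCH)
    return out


def encode_matrix(strings, alphabet: str, nomatch: str = "?"):
    """Pack strings into a padded uint8 matrix plus a length vector."""
    n = len(strings)
    maxlen = max((len(s) for s in strings), default=0)
    codes = np.zeros((n, max(1, maxlen)), dtype=np.uint8)
    lengths = np.zeros(n, dtype=np.int64)
    for i, s in enumerate(strings):
        codes[i, : len(s)] = encode_string(s, alphabet, nomatch)
        lengths[i] = len(s)
    return codes, lengths


def banded_global_score(
    a: np.ndarray,
    b: np.ndarray,
    match: float = 5.0,
    mismatch: float = -4.0,
    gap: float = -4.0,
    band: int = 48,
) -> float:
    """Single-pair banded global alignment score."""
    return float(
        _nw_banded(a, b, len(a), len(b), float(match), float(mismatch), float(gap), band)
    )


def banded_score_matrix(
    strings,
    alphabet: str,
    match: float = 5.0,
    mismatch: float = -4.0,
    gap: float = -4.0,
    band: int = 48,
    pair_truncate: bool = True,
    nomatch: str = "?",
) -> np.ndarray:
    """Symmetric all-pairs score matrix in one compiled pass.

    ``pair_truncate`` compares each pair over its common prefix length.
    Self-scores use the closed form (diagonal alignment is optimal).
    """
    if not len(strings):
        return np.zeros((0, 0))
    codes, lengths = encode_matrix(strings, alphabet, nomatch)
    return _score_matrix(
        codes, lengths, float(match), float(mismatch), float(gap), band, pair_truncate
    )
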