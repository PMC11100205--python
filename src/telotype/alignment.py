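"""Pairwise-aligner construction shared by clustering and consensus.

Two scoring schemes are used. Read-vs-read comparison scores every symbol
match +5 with mismatch/gap -4. Consensus building reduces the reward for
canonical-canonical matches to 0 so the alignment is driven by the variant
repeat blocks, not by the abundant canonical spacer between them. Unknown
symbols never match anything, including themselves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .repeat_model import RepeatSet

__all__ = ["ScoringParams", "symbol_aligner", "nucleotide_aligner", "pairwise_symbol_score"]


@dataclass(frozen=True)
class ScoringParams:
    match: int = 5
    mismatch: int = -4
    gap: int = -4
    canonical_match_consensus: int = 0

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch) or self.gap > 0:
            raise ValueError("require match > 0 > mismatch and gap <= 0")


def symbol_substitution_matrix(
    rs: RepeatSet, params: ScoringParams, canonical_match: int | None = None
):
    """Substitution matrix over the symbol alphabet (incl. unknown).

    ``canonical_match`` overrides the canonical-canonical diagonal entry;
    the unknown symbol scores as a mismatch against everything.
    """
    alpha = rs.alphabet
    n = len(alpha)
    data = np.full((n, n), float(params.mismatch))
    for i, sym in enumerate(alpha):
        if sym == rs.unknown_symbol:
            continue
        data[i, i] = float(params.match)
    if canonical_match is not None:
        ci = alpha.index(rs.canonical_symbol)
        data[ci, ci] = float(canonical_match)
    return substitution_matrices.Array(alphabet=alpha, dims=2, data=data)


def symbol_aligner(
    rs: RepeatSet,
    params: ScoringParams | None = None,
    canonical_match: int | None = None,
    gap_tiebreak: float = 0.0,
) -> Align.PairwiseAligner:
    """Global symbol-string aligner under the scheme above.

    ``gap_tiebreak`` is subtracted from the gap score to break exact
    score ties in favour of mismatches over gap pairs. With the
    canonical-match-0 consensus matrix, a deletion+insertion pair (-8)
    ties two mismatches (-8) whenever only canonical symbols lie between
    them, and the arbitrary gap placement corrupts column votes; an
    epsilon penalty removes the degeneracy without affecting any
    non-degenerate alignment.
    """
    params = params or ScoringParams()
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = symbol_substitution_matrix(rs, params, canonical_match)
    aligner.open_gap_score = float(params.gap) - gap_tiebreak
    aligner.extend_gap_score = float(params.gap) - gap_tiebreak
    return aligner


def nucleotide_aligner(params: ScoringParams | None = None) -> Align.PairwiseAligner:
    """Global DNA aligner with the same match/mismatch/gap scheme."""
    params = params or ScoringParams()
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = float(params.match)
    aligner.mismatch_score = float(params.mismatch)
    aligner.open_gap_score = float(params.gap)
    aligner.extend_gap_score = float(params.gap)
    return aligner


def pairwise_symbol_score(a: str, b: str, aligner: Align.PairwiseAligner, gap: float) -> float:
    """Aligner score with the degenerate empty-string cases handled."""
    if not a or not b:
        return gap * (len(a) + len(b))
    return float(aligner.score(a, b))
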