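"""Selection of telomere-bearing reads and boundary localization.

A usable read terminates in telomere sequence on exactly one end and in
non-telomere (subtelomere) sequence on the other. Reads are screened by
counting canonical repeat copies in both orientations, normalized to the
G-strand with the telomere at the 3' end, and the telomere/subtelomere
boundary is localized from the density of repeat-set matches in a sliding
window.

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Tuple

import numpy as np

from .repeat_model import (
    CANONICAL_SEQUENCE,
    RepeatSet,
    reverse_complement,
)

__all__ = [
    "TelomereRead",
    "count_canonical",
    "density_profile",
    "find_boundary",
    "select_reads",
]

logger = logging.getLogger(__name__)

_CANONICAL_RC = reverse_complement(CANONICAL_SEQUENCE)  # CCCTAA


@dataclass
class TelomereRead:
    """A read normalized so its telomere is at the 3' end on the G-strand.

    ``boundary`` is the 0-based index where the telomere+TVR region starts:
    ``seq[:boundary]`` is subtelomere, ``seq[boundary:]`` is telomere+TVR.
    """

    read_id: str
    seq: str
    original_orientation: str  # telomere_at_start | telomere_at_end
    boundary: int
    canonical_count: int

    def __post_init__(self) -> None:
        if not (0 <= self.boundary < len(self.seq)):
            raise ValueError(
                f"boundary {self.boundary} outside read of length {len(self.seq)}"
            )

    @property
    def subtel_seq(self) -> str:
        return self.seq[: self.boundary]

    @property
    def tel_seq(self) -> str:
        return self.seq[self.boundary :]


def _count_nonoverlapping(seq: str, motif: str) -> int:
    count = 0
    start = 0
    while True:
        idx = seq.find(motif, start)
        if idx < 0:
            return count
        count += 1
        start = idx + len(motif)


def count_canonical(seq: str) -> Tuple[int, int]:
    """Non-overlapping copy counts of TTAGGG (fwd) and CCCTAA (rev) in seq."""
    if not seq:
        return (0, 0)
    seq = seq.upper()
    return (
        _count_nonoverlapping(seq, CANONICAL_SEQUENCE),
        _count_nonoverlapping(seq, _CANONICAL_RC),
    )


def repeat_coverage_mask(seq: str, repeat_set: RepeatSet, both_strands: bool = True) -> np.ndarray:
    """Boolean mask of positions covered by any repeat-set match.

    Occurrences of every repeat (and, optionally, its reverse complement)
    are marked, overlaps allowed; this is a coverage question, not a tiling.
    """
    mask = np.zeros(len(seq), dtype=bool)
    seq = seq.upper()
    motifs = {r.sequence for r in repeat_set}
    if both_strands:
        motifs |= {reverse_complement(m) for m in motifs}
    for motif in motifs:
        start = 0
        while True:
            idx = seq.find(motif, start)
            if idx < 0:
                break
            mask[idx : idx + len(motif)] = True
            start = idx + 1
    return mask


def density_profile(
    seq: str,
    repeat_set: RepeatSet,
    window: int = 100,
    both_strands: bool = True,
) -> np.ndarray:
    """Sliding-window telomere-repeat density along a read.

    Entry ``i`` is the fraction of bases in ``seq[i : i + window]`` covered
    by a repeat-set match. A sequence shorter than the window yields a
    single-entry profile over the whole sequence.
    """
    if window < min(len(r.sequence) for r in repeat_set):
        raise ValueError("window smaller than the shortest repeat")
    if not seq:
        return np.zeros(1)
    mask = repeat_coverage_mask(seq, repeat_set, both_strands=both_strands)
    if len(seq) <= window:
        return np.array([mask.mean()])
    kernel = np.ones(window)
    return np.convolve(mask.astype(float), kernel, mode="valid") / window


def find_boundary(profile: np.ndarray, threshold: float = 0.5) -> Optional[int]:
    """Start of the terminal high-density run, assuming telomere at the end.

    Returns the smallest index ``b`` such that the profile stays at or
    above ``threshold`` from ``b`` through the last above-threshold window;
    ``None`` when no window reaches the threshold (no telomere signal).
    Trailing below-threshold windows (read-tip artifacts) are ignored here;
    whether they are tolerable is decided by :func:`select_reads`.
    """
    above = profile >= threshold
    if not above.any():
        return None
    last = int(np.nonzero(above)[0][-1])
    below_before = np.nonzero(~above[: last + 1])[0]
    if len(below_before) == 0:
        return 0
    return int(below_before[-1]) + 1


def select_reads(
    reads: Iterable[Tuple[str, str]],
    repeat_set: RepeatSet,
    min_copies: int = 10,
    min_subtel: int = 1000,
    window: int = 100,
    density_threshold: float = 0.5,
    tip_tolerance: int = 200,
) -> list[TelomereRead]:
    """Select and normalize telomere-spanning reads.

    Parameters mirror the screening rules: at least ``min_copies``
    non-overlapping canonical repeats in one orientation, the telomere
    region flush with exactly one read end (up to ``tip_tolerance`` bases
    of terminal junk tolerated), and at least ``min_subtel`` bases of
    non-telomere sequence on the other end. Retained reads are oriented
    G-strand, telomere at the 3' end.
    """
    out: list[TelomereRead] = []
    for read_id, raw in reads:
        seq = raw.upper()
        if not seq:
            continue
        fwd, rev = count_canonical(seq)
        if fwd >= min_copies and rev >= min_copies:
            logger.info("%s: telomere at both ends, excluded", read_id)
            continue
        if max(fwd, rev) < min_copies:
            continue
        if rev > fwd:
            seq = reverse_complement(seq)
            orientation = "telomere_at_start"
            count = rev
        else:
            orientation = "telomere_at_end"
            count = fwd
        profile = density_profile(seq, repeat_set, window=window)
        b = find_boundary(profile, density_threshold)
        if b is None:
            logger.info("%s: no telomere density signal, excluded", read_id)
            continue
        above = profile >= density_threshold
        last = int(np.nonzero(above)[0][-1])
        tel_end = min(last + window, len(seq))
        if len(seq) - tel_end > tip_tolerance:
            logger.info("%s: telomere not flush with read end, excluded", read_id)
            continue
        if b == 0:
            logger.info("%s: entirely telomeric, no subtelomere anchor, excluded", read_id)
            continue
        if b < min_subtel:
            logger.info("%s: only %dbp subtelomere (<%d), excluded", read_id, b, min_subtel)
            continue
        out.append(
            TelomereRead(
                read_id=read_id,
                seq=seq,
                original_orientation=orientation,
                boundary=b,
                canonical_count=count,
            )
        )
    # deterministic downstream behavior regardless of input order
    out.sort(key=lambda r: r.read_id)
    return out
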