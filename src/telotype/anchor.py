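"""Chromosome-arm assignment of allele clusters via subtelomere alignment.

Every cluster member's subtelomere portion is mapped against a panel of
subtelomere reference sequences (the distal 500kb of each chromosome arm,
taken from one or more telomere-to-telomere assemblies, oriented so the
telomere-adjacent end is 3'). The cluster's arm is the arm most members
map to best; when members' best hits are split or tied across arms —
subtelomeres can be nearly identical between arms — the assignment is
reported as ambiguous with all candidate arms listed.

The built-in mapper is a minimizer seed counter with an edit-distance
refinement for near-ties; an external mapper executable can be plugged in
through the same hit interface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import edlib
import numpy as np
from Bio import SeqIO

from .repeat_model import reverse_complement
from .telomere_scan import TelomereRead

__all__ = [
    "SubtelomereRef",
    "AnchorResult",
    "build_reference",
    "load_reference",
    "write_reference",
    "MinimizerIndex",
    "anchor_cluster",
]

logger = logging.getLogger(__name__)

_VALID_ARMS = {f"chr{c}{a}" for c in list(range(1, 23)) + ["X", "Y"] for a in "pq"}


@dataclass(frozen=True)
class SubtelomereRef:
    """One chromosome-arm subtelomere, telomere-adjacent end at the 3' end."""

    arm: str
    source_assembly: str
    seq: str

    def __post_init__(self) -> None:
        if len(self.seq) > 500_000:
            raise ValueError(f"{self.arm}: subtelomere reference exceeds 500kb")


@dataclass
class AnchorResult:
    """Ranked candidate arms for a cluster.

    ``arms`` is a list of (arm, member_votes, summed_score) sorted best
    first; ``ambiguous`` is true when more than one arm is supported.
    """

    arms: List[Tuple[str, int, float]]
    ambiguous: bool
    unanchored_reason: Optional[str] = None

    @property
    def arm_labels(self) -> List[str]:
        return [a for a, _, _ in self.arms]


def _norm_arm(label: str) -> str:
    label = label if label.startswith("chr") else "chr" + label
    if label not in _VALID_ARMS:
        raise ValueError(f"invalid chromosome-arm label {label!r}")
    return label


def build_reference(
    assembly_fastas: Dict[str, Union[str, Path]],
    span: int = 500_000,
) -> List[SubtelomereRef]:
    """Extract both arm subtelomeres from whole-chromosome FASTA assemblies.

    ``assembly_fastas`` maps an assembly name to a FASTA whose records are
    named by chromosome (e.g. "chr1"). The q-arm reference is the last
    ``span`` bases as-is; the p-arm reference is the first ``span`` bases
    reverse-complemented, so every reference ends at its telomere junction.
    """
    refs: List[SubtelomereRef] = []
    for assembly, path in sorted(assembly_fastas.items()):
        for rec in SeqIO.parse(str(path), "fasta"):
            chrom = rec.id if rec.id.startswith("chr") else "chr" + rec.id
            seq = str(rec.seq).upper()
            if len(seq) < 2 * span:
                logger.warning(
                    "%s %s is %dbp (<2x span): p and q references overlap",
                    assembly, chrom, len(seq),
                )
            p_seq = reverse_complement(seq[: min(span, len(seq))])
            q_seq = seq[-min(span, len(seq)) :]
            refs.append(SubtelomereRef(_norm_arm(chrom + "p"), assembly, p_seq))
            refs.append(SubtelomereRef(_norm_arm(chrom + "q"), assembly, q_seq))
    return refs


def write_reference(refs: Sequence[SubtelomereRef], path: Union[str, Path]) -> None:
    """Write a reference panel as multi-FASTA with '<assembly>_<arm>' ids."""
    with open(path, "w") as fh:
        for r in refs:
            fh.write(f">{r.source_assembly}_{r.arm}\n")
            for i in range(0, len(r.seq), 80):
                fh.write(r.seq[i : i + 80] + "\n")


def load_reference(path: Union[str, Path]) -> List[SubtelomereRef]:
    """Load a panel from multi-FASTA with record ids '<assembly>_<arm>'."""
    refs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        assembly, _, arm = rec.id.rpartition("_")
        refs.append(SubtelomereRef(_norm_arm(arm), assembly or "ref", str(rec.seq).upper()))
    return refs


# ---------------------------------------------------------------------------
# Built-in mapper: minimizer seeding + edit-distance refinement


def _kmer_hash(x: int) -> int:
    # splitmix64-style deterministic mixer (Python's str hash is randomized)
    x = (x ^ (x >> 30)) * 0xBF58476D1CE4E5B9 & 0xFFFFFFFFFFFFFFFF
    x = (x ^ (x >> 27)) * 0x94D049BB133111EB & 0xFFFFFFFFFFFFFFFF
    return x ^ (x >> 31)


_BASE2BITS = {"A": 0, "C": 1, "G": 2, "T": 3}


def minimizers(seq: str, k: int = 15, w: int = 10) -> set[int]:
    """Deterministic (k,w)-minimizer hash sketch of a sequence."""
    n = len(seq)
    if n < k:
        return set()
    hashes: List[int] = []
    val = 0
    mask = (1 << (2 * k)) - 1
    run = 0  # length of current ACGT-only run
    for ch in seq:
        b = _BASE2BITS.get(ch)
        if b is None:
            run = 0
            hashes.append(-1)
            continue
        val = ((val << 2) | b) & mask
        run += 1
        hashes.append(_kmer_hash(val) if run >= k else -1)
    out: set[int] = set()
    for i in range(k - 1, n - w + 1):
        window = [h for h in hashes[i : i + w] if h >= 0]
        if window:
            out.add(min(window))
    return out


class MinimizerIndex:
    """Minimizer sketches of a reference panel, queried by shared-seed count."""

    def __init__(self, refs: Sequence[SubtelomereRef], k: int = 15, w: int = 10):
        self.refs = list(refs)
        self.k = k
        self.w = w
        self._sketches = [minimizers(r.seq, k, w) for r in self.refs]

    def seed_scores(self, query: str) -> np.ndarray:
        qset = minimizers(query, self.k, self.w)
        return np.array([len(qset & s) for s in self._sketches], dtype=float)

    def map_read(
        self, query: str, tie_margin: float = 0.95, refine: bool = True
    ) -> List[Tuple[int, float]]:
        """Best reference hits for a query: list of (ref index, score).

        Seed counting shortlists references within ``tie_margin`` of the
        best; near-ties are refined by semi-global edit distance (the
        query may fall anywhere inside the reference), keeping every
        reference within a small absolute edit-distance margin of the
        best. Multiple survivors mean the query maps ambiguously.
        """
        scores = self.seed_scores(query)
        best = scores.max() if scores.size else 0.0
        if best <= 0:
            return []
        cand = [i for i, s in enumerate(scores) if s >= tie_margin * best]
        if not refine or len(cand) == 1:
            return [(i, float(scores[i])) for i in sorted(cand, key=lambda i: -scores[i])]
        dists = {}
        for i in cand:
            res = edlib.align(query, self.refs[i].seq, mode="HW", task="distance")
            dists[i] = res["editDistance"]
        dbest = min(dists.values())
        margin = max(2.0, 0.005 * len(query))
        keep = [i for i in cand if dists[i] <= dbest + margin]
        keep.sort(key=lambda i: (dists[i], -scores[i], i))
        return [(i, float(len(query) - dists[i])) for i in keep]


def anchor_cluster(
    members: Sequence[TelomereRead],
    refs: Sequence[SubtelomereRef],
    min_subtel: int = 1000,
    index: Optional[MinimizerIndex] = None,
    tie_margin: float = 0.95,
) -> AnchorResult:
    """Assign a cluster to chromosome arm(s) by its members' subtelomeres.

    Reads with less than ``min_subtel`` bp of subtelomere are skipped.
    Hits to the same arm from different assemblies are pooled. Candidate
    arms are those supported by a majority of voting members; the result
    is ambiguous when more than one arm survives (near-identical
    subtelomere references, or members split across arms).
    """
    if index is None:
        index = MinimizerIndex(refs)
    votes: Dict[str, int] = {}
    score_sum: Dict[str, float] = {}
    n_voting = 0
    for m in members:
        sub = m.subtel_seq
        if len(sub) < min_subtel:
            continue
        hits = index.map_read(sub, tie_margin=tie_margin)
        if not hits:
            continue
        n_voting += 1
        arms_here: Dict[str, float] = {}
        for ref_i, score in hits:
            arm = index.refs[ref_i].arm
            arms_here[arm] = max(arms_here.get(arm, 0.0), score)
        for arm, sc in arms_here.items():
            votes[arm] = votes.get(arm, 0) + 1
            score_sum[arm] = score_sum.get(arm, 0.0) + sc
    if n_voting == 0:
        reason = (
            "no member has >= %dbp of subtelomere sequence" % min_subtel
            if any(len(m.subtel_seq) < min_subtel for m in members)
            else "no member produced an alignment to the reference panel"
        )
        return AnchorResult([], False, unanchored_reason=reason)
    ranked = sorted(votes, key=lambda a: (-votes[a], -score_sum[a], a))
    supported = [a for a in ranked if votes[a] * 2 > n_voting] or ranked[:1]
    arms = [(a, votes[a], score_sum[a]) for a in supported]
    return AnchorResult(arms, ambiguous=len(arms) > 1)
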