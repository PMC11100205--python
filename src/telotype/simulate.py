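"""Synthetic telomere-read generator with full ground truth.

Each simulated allele is a molecule of three parts: a unique subtelomere
flank, a TVR region decoded from a symbol pattern (blocks of variant
repeats interspersed with canonical TTAGGG), and a pure canonical telomere
whose per-read length is drawn from a normal distribution — telomere
length varies from cell to cell within one sample. Reads are emitted on a
random strand, either as complete molecules (telomere-capture-like) or as
random fragments (WGS-like), with substitution and indel errors; indel
probability is inflated inside homopolymer runs, the dominant error mode
of long-read sequencing in telomeres.

Everything emitted is recorded in a :class:`SimTruth` so each pipeline
stage can be checked against known answers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .repeat_model import CANONICAL_SEQUENCE, RepeatSet, load_repeat_set, reverse_complement

__all__ = [
    "SimAllele",
    "SimRead",
    "SimTruth",
    "random_tvr_pattern",
    "decode_pattern",
    "make_alleles",
    "simulate_sample",
    "simulate_trio",
    "write_fastq",
]

#: Default variant-symbol weights for generated TVR patterns, loosely
#: following the composition seen in human TVR regions (G- and J-type most
#: common, then C-type, then rarer substitution variants).
DEFAULT_VARIANT_WEIGHTS: Dict[str, float] = {
    "E": 7.0,  # TGAGGG
    "F": 7.0,  # TTGGGG
    "D": 4.0,  # TCAGGG
    "G": 1.5,
    "H": 1.5,
    "I": 1.0,
    "K": 1.0,
    "L": 1.0,
    "M": 1.0,
}

_ARM_ORDER = [f"chr{c}{a}" for c in list(range(1, 23)) + ["X", "Y"] for a in "pq"]


@dataclass(frozen=True)
class SimAllele:
    """Ground-truth telomere allele: one haplotype of one chromosome arm."""

    allele_id: str
    arm: str
    subtel_seq: str
    tvr_pattern: str  # symbol string, subtelomere-proximal first
    tl_mean: float
    tl_sd: float

    def __post_init__(self) -> None:
        if self.tl_mean <= 0:
            raise ValueError("tl_mean must be positive")


@dataclass(frozen=True)
class SimRead:
    """Provenance of one emitted read (molecule coordinates, pre-error)."""

    read_id: str
    allele_id: str
    strand: str  # + emitted as molecule, - as reverse complement
    subtel_len: int
    tvr_len: int
    tl: int
    frag_start: int  # 0 for complete molecules
    frag_end: int
    n_errors: int


@dataclass
class SimTruth:
    alleles: List[SimAllele]
    reads: List[SimRead]

    def reads_of(self, allele_id: str) -> List[SimRead]:
        return [r for r in self.reads if r.allele_id == allele_id]


def random_tvr_pattern(
    rng: np.random.Generator,
    n_blocks_range: Tuple[int, int] = (3, 10),
    block_len_range: Tuple[int, int] = (1, 20),
    spacer_range: Tuple[int, int] = (2, 15),
    variant_weights: Optional[Dict[str, float]] = None,
) -> str:
    """Random TVR symbol pattern: variant blocks separated by canonical runs.

    The pattern starts with a short canonical lead and ends at its most
    distal variant block — the pure telomere is appended separately at
    simulation time. Only substitution-type variants are drawn, so the
    pattern survives encoding (indel-variant singletons would be pruned as
    presumed errors).
    """
    weights = variant_weights or DEFAULT_VARIANT_WEIGHTS
    syms = sorted(weights)
    p = np.array([weights[s] for s in syms])
    p = p / p.sum()
    n_blocks = int(rng.integers(n_blocks_range[0], n_blocks_range[1] + 1))
    parts: List[str] = ["C" * int(rng.integers(spacer_range[0], spacer_range[1] + 1))]
    for b in range(n_blocks):
        sym = str(rng.choice(syms, p=p))
        parts.append(sym * int(rng.integers(block_len_range[0], block_len_range[1] + 1)))
        if b < n_blocks - 1:
            parts.append("C" * int(rng.integers(spacer_range[0], spacer_range[1] + 1)))
    return "".join(parts)


def decode_pattern(pattern: str, rs: Optional[RepeatSet] = None) -> str:
    """Decode a symbol pattern to DNA using each symbol's primary sequence."""
    rs = rs or load_repeat_set()
    return "".join(rs.decode_symbol(s) for s in pattern)


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def make_alleles(
    n: int,
    seed: Union[int, np.random.Generator] = 0,
    subtel_len: int = 2000,
    tl_mean_range: Tuple[float, float] = (2000.0, 6000.0),
    tl_sd: float = 300.0,
    arms: Optional[Sequence[str]] = None,
    **pattern_kwargs,
) -> List[SimAllele]:
    """Generate ``n`` alleles with distinct subtelomeres and TVR patterns."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if arms is None:
        arms = [_ARM_ORDER[i % len(_ARM_ORDER)] for i in range(n)]
    alleles = []
    for i in range(n):
        alleles.append(
            SimAllele(
                allele_id=f"allele{i:03d}",
                arm=arms[i],
                subtel_seq=random_dna(rng, subtel_len),
                tvr_pattern=random_tvr_pattern(rng, **pattern_kwargs),
                tl_mean=float(rng.uniform(*tl_mean_range)),
                tl_sd=tl_sd,
            )
        )
    return alleles


def _homopolymer_mask(codes: np.ndarray, min_run: int = 3) -> np.ndarray:
    """True at positions inside a homopolymer run of >= min_run bases."""
    n = len(codes)
    if n == 0:
        return np.zeros(0, dtype=bool)
    change = np.empty(n, dtype=bool)
    change[0] = True
    change[1:] = codes[1:] != codes[:-1]
    run_id = np.cumsum(change) - 1
    run_lengths = np.bincount(run_id)
    return run_lengths[run_id] >= min_run


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def apply_errors(
    seq: str,
    rng: np.random.Generator,
    error_rate: float,
    homopolymer_bias: float = 3.0,
    sub_fraction: float = 0.4,
) -> Tuple[str, int]:
    """Inject substitutions and indels; returns (mutated seq, error count).

    Per-base substitution probability is ``error_rate * sub_fraction``;
    indel probability is ``error_rate * (1 - sub_fraction)``, multiplied by
    ``homopolymer_bias`` inside homopolymer runs of three or more bases
    (insertions and deletions equally likely; insertions duplicate the
    local base, the homopolymer error signature).
    """
    if error_rate <= 0 or not seq:
        return seq, 0
    codes = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    n = len(codes)
    hp = _homopolymer_mask(codes)
    p_sub = np.full(n, error_rate * sub_fraction)
    p_ind = np.full(n, error_rate * (1.0 - sub_fraction))
    p_ind[hp] *= homopolymer_bias
    u = rng.random(n)
    sub_at = u < p_sub
    ind_at = (~sub_at) & (u < p_sub + p_ind)
    # substitutions: replace with a uniformly random different base
    if sub_at.any():
        idx = np.nonzero(sub_at)[0]
        newb = _BASES[rng.integers(0, 4, size=len(idx))]
        same = newb == codes[idx]
        while same.any():
            newb[same] = _BASES[rng.integers(0, 4, size=int(same.sum()))]
            same = newb == codes[idx]
        codes[idx] = newb
    # indels are rare; apply positionally in reverse so indices stay valid
    out = codes.tolist()
    ind_idx = np.nonzero(ind_at)[0]
    is_ins = rng.random(len(ind_idx)) < 0.5
    n_err = int(sub_at.sum()) + len(ind_idx)
    for pos, ins in zip(ind_idx[::-1], is_ins[::-1]):
        if ins:
            out.insert(int(pos), out[int(pos)])
        else:
            del out[int(pos)]
    return bytes(out).decode(), n_err


def simulate_sample(
    alleles: Sequence[SimAllele],
    coverage: float = 30.0,
    error_rate: float = 0.01,
    homopolymer_bias: float = 3.0,
    sub_fraction: float = 0.4,
    seed: int = 0,
    wgs_fragmentation: bool = False,
    read_len_mean: float = 25_000.0,
    read_len_sd: float = 5_000.0,
    depth_model: str = "fixed",
    rs: Optional[RepeatSet] = None,
) -> Tuple[List[Tuple[str, str]], SimTruth]:
    """Emit reads for a set of alleles, with ground truth.

    Each allele receives ``round(coverage / 2)`` reads: sample coverage is
    diploid, so one haplotype sees half of it. ``depth_model="poisson"``
    instead draws each allele's read count from Poisson(coverage/2),
    emulating the per-allele depth fluctuation of a real sequencing run.
    Default fragmentation is complete molecules (as from telomere
    capture); ``wgs_fragmentation`` instead emits random fragments of
    normal length, many of which only partially cover the telomere.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if error_rate >= 0.05:
        raise ValueError("error model intended for low-error long reads (<5%)")
    if depth_model not in ("fixed", "poisson"):
        raise ValueError(f"unknown depth_model {depth_model!r}")
    rs = rs or load_repeat_set()
    rng = np.random.default_rng(seed)
    reads: List[Tuple[str, str]] = []
    truth_reads: List[SimRead] = []
    for allele in alleles:
        if depth_model == "poisson":
            n_reads = int(rng.poisson(coverage / 2.0))
        else:
            n_reads = max(1, round(coverage / 2.0))
        tvr_seq = decode_pattern(allele.tvr_pattern, rs)
        for i in range(n_reads):
            tl = max(0, int(round(rng.normal(allele.tl_mean, allele.tl_sd))))
            n_rep = -(-tl // len(CANONICAL_SEQUENCE))
            tel_seq = (CANONICAL_SEQUENCE * n_rep)[:tl]
            molecule = allele.subtel_seq + tvr_seq + tel_seq
            if wgs_fragmentation:
                flen = max(500, int(round(rng.normal(read_len_mean, read_len_sd))))
                start = int(rng.integers(0, max(1, len(molecule))))
                frag = molecule[start : start + flen]
                frag_start, frag_end = start, min(start + flen, len(molecule))
            else:
                frag = molecule
                frag_start, frag_end = 0, len(molecule)
            seq, n_err = apply_errors(frag, rng, error_rate, homopolymer_bias, sub_fraction)
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                seq = reverse_complement(seq)
            read_id = f"{allele.allele_id}_read{i:04d}"
            reads.append((read_id, seq))
            truth_reads.append(
                SimRead(
                    read_id=read_id,
                    allele_id=allele.allele_id,
                    strand=strand,
                    subtel_len=len(allele.subtel_seq),
                    tvr_len=len(tvr_seq),
                    tl=tl,
                    frag_start=frag_start,
                    frag_end=frag_end,
                    n_errors=n_err,
                )
            )
    return reads, SimTruth(list(alleles), truth_reads)


def _variant_blocks(pattern: str, canonical_symbol: str = "C") -> List[Tuple[int, int]]:
    """(start, end) of maximal non-canonical runs in a symbol pattern."""
    blocks = []
    start = None
    for i, s in enumerate(pattern + canonical_symbol):
        if s != canonical_symbol and start is None:
            start = i
        elif s == canonical_symbol and start is not None:
            blocks.append((start, i))
            start = None
    return blocks


def delete_distal_variant_block(pattern: str, canonical_symbol: str = "C") -> str:
    """Remove the most distal (3'-most) variant block from a pattern."""
    blocks = _variant_blocks(pattern, canonical_symbol)
    if not blocks:
        return pattern
    s, e = blocks[-1]
    return pattern[:s] + pattern[e:]


def simulate_trio(
    parent1: Sequence[SimAllele],
    parent2: Sequence[SimAllele],
    de_novo_distal_deletion_prob: float = 0.0,
    seed: int = 0,
) -> List[SimAllele]:
    """Child alleles: one inherited per arm per parent.

    With the stated probability an inherited TVR pattern loses its most
    distal variant block — the kind of de novo change seen at the
    telomere-proximal edge of real inherited TVR regions.
    """
    rng = np.random.default_rng(seed)

    def by_arm(alleles):
        d: Dict[str, List[SimAllele]] = {}
        for a in alleles:
            d.setdefault(a.arm, []).append(a)
        return d

    p1, p2 = by_arm(parent1), by_arm(parent2)
    if set(p1) != set(p2):
        raise ValueError("parents must cover the same chromosome arms")
    child: List[SimAllele] = []
    for arm in sorted(p1):
        for tag, pool in (("p1", p1[arm]), ("p2", p2[arm])):
            src = pool[int(rng.integers(0, len(pool)))]
            pattern = src.tvr_pattern
            if rng.random() < de_novo_distal_deletion_prob:
                pattern = delete_distal_variant_block(pattern)
            child.append(
                SimAllele(
                    allele_id=f"child_{arm}_{tag}",
                    arm=arm,
                    subtel_seq=src.subtel_seq,
                    tvr_pattern=pattern,
                    tl_mean=src.tl_mean,
                    tl_sd=src.tl_sd,
                )
            )
    return child


def write_fastq(reads: Sequence[Tuple[str, str]], path: Union[str, Path]) -> None:
    """Write reads as FASTQ (gzipped when the path ends in .gz)."""
    import gzip

    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "wt") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_truth_tsv(truth: SimTruth, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tallele_id\tarm\tstrand\tsubtel_len\ttvr_len\ttl\tn_errors\n")
        arm_of = {a.allele_id: a.arm for a in truth.alleles}
        for r in truth.reads:
            fh.write(
                f"{r.read_id}\t{r.allele_id}\t{arm_of[r.allele_id]}\t{r.strand}\t"
                f"{r.subtel_len}\t{r.tvr_len}\t{r.tl}\t{r.n_errors}\n"
            )
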