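"""Sequence input, the allele report, and per-allele repeat plots."""

from __future__ import annotations

import gzip
import json
import logging
from pathlib import Path
from typing import Iterator, List, Optional, Sequence, Tuple, Union

import pandas as pd

from .allele_cluster import AlleleCluster
from .repeat_model import RepeatSet, load_repeat_set, reverse_complement

__all__ = [
    "read_sequences",
    "write_report",
    "read_report",
    "render_allele_plot",
    "write_run_sidecar",
    "REPORT_COLUMNS",
]

logger = logging.getLogger(__name__)

REPORT_COLUMNS = [
    "sample",
    "cluster_id",
    "arms",
    "ambiguous",
    "read_count",
    "blank",
    "tvr_len_bp",
    "tvr_consensus",
    "atl_method",
    "atl_bp",
    "atl_distribution",
]


def _open_text(path: str):
    return gzip.open(path, "rt") if path.endswith(".gz") else open(path)


def read_sequences(path: Union[str, Path]) -> Iterator[Tuple[str, str]]:
    """Yield (read_id, sequence) from FASTQ/FASTA (plain or gzip) or SAM/BAM.

    Alignment information in SAM/BAM is ignored; the stored query sequence
    is restored to its original strand using the reverse-strand flag, and
    secondary/supplementary records are skipped.
    """
    path = str(path)
    stem = path[:-3] if path.endswith(".gz") else path
    suffix = Path(stem).suffix.lower()
    if suffix in (".fq", ".fastq", ".fa", ".fasta", ".fna"):
        from Bio import SeqIO

        fmt = "fastq" if suffix in (".fq", ".fastq") else "fasta"
        with _open_text(path) as fh:
            for rec in SeqIO.parse(fh, fmt):
                yield rec.id, str(rec.seq).upper()
    elif suffix in (".bam", ".sam", ".cram"):
        import pysam

        save = pysam.set_verbosity(0)  # suppress missing-index chatter
        with pysam.AlignmentFile(path, check_sq=False) as bam:
            pysam.set_verbosity(save)
            for rec in bam.fetch(until_eof=True):
                if rec.is_secondary or rec.is_supplementary:
                    continue
                seq = rec.query_sequence
                if not seq:
                    continue
                if rec.is_reverse:
                    seq = reverse_complement(seq)
                yield rec.query_name, seq.upper()
    else:
        raise ValueError(f"unrecognized sequence file type: {path}")


def _cluster_row(cluster: AlleleCluster, sample: str) -> dict:
    anchor = cluster.anchor
    arms = ",".join(anchor.arm_labels) if anchor and anchor.arms else "unanchored"
    tvr = cluster.tvr
    atl = cluster.atl
    return {
        "sample": sample,
        "cluster_id": cluster.cluster_id,
        "arms": arms,
        "ambiguous": bool(anchor.ambiguous) if anchor else False,
        "read_count": cluster.read_count,
        "blank": cluster.blank,
        "tvr_len_bp": int(tvr.tvr_boundary_bp) if tvr else 0,
        "tvr_consensus": cluster.consensus.symbols if cluster.consensus else "",
        "atl_method": atl.method if atl else "",
        "atl_bp": round(float(atl.representative_bp), 1) if atl else 0.0,
        "atl_distribution": ",".join(str(x) for x in atl.lengths_bp) if atl else "",
    }


def write_report(
    clusters: Sequence[AlleleCluster],
    path: Union[str, Path],
    sample: str = "sample",
) -> pd.DataFrame:
    """Write the per-allele TSV report; returns it as a DataFrame.

    One row per cluster, sorted by arm then TVR length descending.
    """
    rows = [_cluster_row(c, sample) for c in clusters]
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    if len(df):
        df = df.sort_values(
            ["arms", "tvr_len_bp", "cluster_id"],
            ascending=[True, False, True],
            kind="mergesort",
        ).reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False)
    return df


def read_report(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(
        path,
        sep="\t",
        dtype={"tvr_consensus": str, "atl_distribution": str},
        keep_default_na=False,
    )


def render_allele_plot(
    cluster: AlleleCluster,
    path: Union[str, Path],
    rs: Optional[RepeatSet] = None,
    max_reads: int = 40,
) -> None:
    """Draw the cluster's reads and consensus as repeat-colorized bars.

    Each read is a horizontal bar whose segments are colored by the repeat
    symbol covering them; the consensus track is drawn on top with a tick
    at the TVR boundary.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rs = rs or load_repeat_set()
    tracks: List[Tuple[str, object]] = [
        (read.read_id, ss) for read, ss in cluster.members[:max_reads]
    ]
    if cluster.consensus is not None:
        tracks.append(("consensus", cluster.consensus))
    fig, ax = plt.subplots(figsize=(12, max(2, 0.3 * len(tracks) + 1)))
    for y, (label, ss) in enumerate(tracks):
        for sym, (s, e) in zip(ss.symbols, ss.base_offsets):
            ax.barh(y, e - s, left=s, height=0.8, color=rs.color(sym), linewidth=0)
    ax.set_yticks(range(len(tracks)))
    ax.set_yticklabels([t[0] for t in tracks], fontsize=6)
    if cluster.tvr is not None and cluster.tvr.tvr_boundary_bp > 0:
        ax.axvline(cluster.tvr.tvr_boundary_bp, color="black", linestyle="--", lw=1)
    ax.set_xlabel("bp from subtelomere/TVR junction")
    ax.set_title(cluster.cluster_id)
    ax.invert_yaxis()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def write_run_sidecar(params: dict, path: Union[str, Path]) -> None:
    """Machine-readable JSON sidecar with the run's parameters."""
    from . import __version__

    payload = {"telotype_version": __version__, "parameters": params}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
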