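"""End-to-end orchestration: reads in, allele report out.

Stage order: read selection → TVR symbol encoding → TVR clustering →
cluster refinement → blank-cluster regrouping by subtelomere → consensus,
TVR boundary and ATL per cluster → subtelomere anchoring → report. Every
stage logs its in/out counts; the whole run is deterministic for a fixed
configuration.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .alignment import ScoringParams
from .allele_cluster import (
    AlleleCluster,
    cluster_reads,
    flag_blank,
    pairwise_score_matrix,
    refine_cluster,
    score_to_distance,
    subtelomere_distance_matrix,
)
from .anchor import MinimizerIndex, SubtelomereRef, anchor_cluster, load_reference
from .consensus_atl import atl_distribution, msa_consensus, tvr_boundary
from .repeat_model import RepeatSet, load_repeat_set
from .report_io import read_sequences, render_allele_plot, write_report, write_run_sidecar
from .telomere_scan import TelomereRead, select_reads
from .tvr_encode import SymbolString, encode_tel_region

__all__ = ["RunConfig", "run", "cluster_sample"]

logger = logging.getLogger(__name__)

Member = Tuple[TelomereRead, SymbolString]


@dataclass
class RunConfig:
    """All knobs of a pipeline run; serialized into the run's JSON sidecar."""

    input: Optional[str] = None
    subtel_ref: Optional[str] = None
    out_dir: str = "telotype_out"
    sample: str = "sample"
    repeat_config: Optional[str] = None
    # read selection
    min_copies: int = 10
    min_subtel: int = 1000
    window: int = 100
    tel_density: float = 0.5
    tip_tolerance: int = 200
    # clustering
    cut: float = 0.40
    aggressive_cut: float = 0.25
    subtel_cut: float = 0.25
    min_reads: int = 3
    min_variants: int = 5
    max_tvr_symbols: int = 500
    subtel_compare_bp: int = 1000
    # consensus / ATL
    boundary_q: float = 0.95
    atl_method: str = "p75"
    # plumbing
    plots: bool = False
    seed: int = 0
    log_level: str = "INFO"


def cluster_sample(
    selected: Sequence[TelomereRead],
    rs: RepeatSet,
    config: RunConfig,
    params: Optional[ScoringParams] = None,
) -> Tuple[List[AlleleCluster], List[Member]]:
    """TVR encoding, clustering, refinement and blank regrouping.

    Returns finalized (but not yet consensus-annotated) clusters plus the
    reads left unassigned (groups smaller than ``min_reads``).
    """
    params = params or ScoringParams()
    members: List[Member] = [
        (read, encode_tel_region(read.tel_seq, rs)) for read in selected
    ]
    if not members:
        return [], []

    strings = [ss.symbols for _, ss in members]
    S = pairwise_score_matrix(strings, rs, params, config.max_tvr_symbols)
    D, valid = score_to_distance(S)
    kept = [m for m, v in zip(members, valid) if v]
    unassigned: List[Member] = [m for m, v in zip(members, valid) if not v]
    prelim_idx, un_idx = cluster_reads(D, cut=config.cut, min_reads=config.min_reads)
    unassigned.extend(kept[i] for i in un_idx)
    logger.info("preliminary clustering: %d clusters from %d reads", len(prelim_idx), len(kept))

    blank_pool: List[Member] = []
    refined: List[List[Member]] = []
    for idx in prelim_idx:
        group = [kept[i] for i in idx]
        counts = [ss.variant_count(rs) for _, ss in group]
        if np.median(counts) < config.min_variants:
            # indistinct TVR: these reads are grouped by subtelomere instead
            blank_pool.extend(group)
            continue
        kept_rows = np.nonzero(valid)[0]
        sub = S[np.ix_(kept_rows[idx], kept_rows[idx])]
        subclusters, un = refine_cluster(
            group,
            rs,
            aggressive_cut=config.aggressive_cut,
            subtel_cut=config.subtel_cut,
            min_reads=config.min_reads,
            params=params,
            max_symbols=config.max_tvr_symbols,
            subtel_compare_bp=config.subtel_compare_bp,
            scores=sub,
        )
        refined.extend(subclusters)
        unassigned.extend(un)

    if blank_pool:
        reads = [r for r, _ in blank_pool]
        Dsub = subtelomere_distance_matrix(reads, params, config.subtel_compare_bp)
        sub_idx, un_idx = cluster_reads(Dsub, cut=config.subtel_cut, min_reads=config.min_reads)
        refined.extend([blank_pool[i] for i in idx] for idx in sub_idx)
        unassigned.extend(blank_pool[i] for i in un_idx)

    for group in refined:
        group.sort(key=lambda m: m[0].read_id)
    refined.sort(key=lambda g: g[0][0].read_id)
    clusters = [
        flag_blank(AlleleCluster(cluster_id=f"cluster{i:03d}", members=g), rs, config.min_variants)
        for i, g in enumerate(refined)
    ]
    logger.info(
        "refinement: %d clusters (%d blank), %d reads unassigned",
        len(clusters),
        sum(c.blank for c in clusters),
        len(unassigned),
    )
    return clusters, unassigned


def annotate_clusters(
    clusters: Sequence[AlleleCluster],
    rs: RepeatSet,
    config: RunConfig,
    refs: Optional[Sequence[SubtelomereRef]] = None,
    params: Optional[ScoringParams] = None,
) -> None:
    """Fill consensus, TVR boundary, ATL distribution and anchor in place."""
    params = params or ScoringParams()
    index = MinimizerIndex(refs) if refs else None
    for cluster in clusters:
        strings = [ss for _, ss in cluster.members]
        consensus, support = msa_consensus(
            strings, rs, params, max_symbols=config.max_tvr_symbols, return_support=True
        )
        cluster.consensus = consensus
        cluster.tvr = tvr_boundary(consensus, rs, q=config.boundary_q, support=support)
        cluster.atl = atl_distribution(
            strings, cluster.tvr, rs, method=config.atl_method, params=params
        )
        if index is not None:
            cluster.anchor = anchor_cluster(
                [r for r, _ in cluster.members],
                index.refs,
                min_subtel=config.min_subtel,
                index=index,
            )


def run(
    config: RunConfig,
    reads: Optional[Sequence[Tuple[str, str]]] = None,
    refs: Optional[Sequence[SubtelomereRef]] = None,
):
    """Execute the full pipeline; returns (clusters, report DataFrame).

    ``reads`` and ``refs`` may be passed directly (library use) or read
    from ``config.input`` / ``config.subtel_ref``.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    rs = load_repeat_set(config.repeat_config)
    if reads is None:
        if config.input is None:
            raise ValueError("no input reads provided")
        reads = list(read_sequences(config.input))
    if refs is None and config.subtel_ref:
        refs = load_reference(config.subtel_ref)

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    selected = select_reads(
        reads,
        rs,
        min_copies=config.min_copies,
        min_subtel=config.min_subtel,
        window=config.window,
        density_threshold=config.tel_density,
        tip_tolerance=config.tip_tolerance,
    )
    logger.info("selected %d/%d telomere-spanning reads", len(selected), len(reads))
    if not selected:
        logger.warning("no telomere-spanning reads found; writing empty report")

    clusters, unassigned = cluster_sample(selected, rs, config)
    annotate_clusters(clusters, rs, config, refs=refs)

    report = write_report(clusters, out_dir / "allele_report.tsv", sample=config.sample)
    write_run_sidecar(asdict(config), out_dir / "run_parameters.json")
    if config.plots:
        plot_dir = out_dir / "plots"
        plot_dir.mkdir(exist_ok=True)
        for cluster in clusters:
            render_allele_plot(cluster, plot_dir / f"{cluster.cluster_id}.png", rs)
    return clusters, report
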