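"""Batching and pipeline orchestration.

Query sequences are processed in batches to bound memory. Within a batch the
unit of parallel work is one (query sequence, anchor partition) pair, pooled
across every sequence of the batch, so a batch with few long sequences still
saturates the workers. All results are reassembled in input order: the PAF
output is byte-identical for every worker count and every batch size.
"""
from __future__ import annotations

import os
import sys
import time
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

from ._pool import run_pool
from .chain_classify import mark_primary_fast, overlap_fraction
from .chaining import (
    Chain,
    ChainFlag,
    ChainParams,
    chain_partition,
    partition_anchors,
    sort_chains,
)
from .extension import AlignParams, compute_mapq, extend_chain
from .genome_io import PafRecord, SequenceRecord, read_fasta
from .seeding import IndexParams, build_index, collect_anchors


@dataclass
class BatchPlan:
    batches: List[List[int]]
    batch_bases: int


@dataclass
class RunConfig:
    workers: int = field(default_factory=lambda: os.cpu_count() or 1)
    seed: int = 11
    index_params: IndexParams = field(default_factory=IndexParams)
    chain_params: ChainParams = field(default_factory=ChainParams)
    align_params: AlignParams = field(default_factory=AlignParams)
    mask_level: float = 0.5
    no_secondary: bool = False
    batch_bases: int = 500_000_000
    verbose: bool = False

    def __post_init__(self):
        if self.workers < 1:
            raise ValueError("workers must be >= 1")


def plan_batches(queries: Sequence[SequenceRecord], batch_bases: int) -> BatchPlan:
    """Greedy fill in input order; an oversize sequence gets its own batch."""
    batches: List[List[int]] = []
    current: List[int] = []
    total = 0
    for i, rec in enumerate(queries):
        if current and total + rec.length > batch_bases:
            batches.append(current)
            current, total = [], 0
        current.append(i)
        total += rec.length
        if rec.length > batch_bases:  # singleton rule
            batches.append(current)
            current, total = [], 0
    if current:
        batches.append(current)
    return BatchPlan(batches=batches, batch_bases=batch_bases)


def _log(config: RunConfig, msg: str) -> None:
    if config.verbose:
        print(f"[wgalign] {msg}", file=sys.stderr)


def _best_secondary(primary: Chain, secondaries: List[Chain], mask_level: float):
    best = None
    for s in secondaries:
        if overlap_fraction(primary, s) > mask_level:
            if best is None or s.score > best:
                best = s.score
    return best


def align_records(
    ref: Sequence[SequenceRecord],
    queries: Sequence[SequenceRecord],
    config: RunConfig,
) -> List[PafRecord]:
    """Full seed -> partition -> chain -> mark -> extend pipeline."""
    t0 = time.perf_counter()
    index = build_index(ref, config.index_params)
    _log(config, f"indexed {len(ref)} sequence(s) in {time.perf_counter() - t0:.2f}s")
    plan = plan_batches(queries, config.batch_bases)
    records: List[PafRecord] = []
    for batch in plan.batches:
        # seeding: per-query anchors, split into partitions
        per_query_parts = []
        tasks = []
        for qi in batch:
            anchors = collect_anchors(queries[qi], index, workers=config.workers)
            parts = partition_anchors(anchors, index.T)
            _log(
                config,
                f"{queries[qi].name}: {anchors.shape[0]} anchors, "
                f"{len(parts)} partition(s) "
                f"(sizes {[p.anchors.shape[0] for p in parts]})",
            )
            per_query_parts.append((qi, parts))
            tasks.extend((qi, p) for p in parts)
        # chaining: (query, partition) units pooled across the batch
        results = run_pool(
            tasks,
            lambda t: chain_partition(t[1], config.chain_params),
            workers=config.workers,
            size=lambda t: t[1].anchors.shape[0],
        )
        by_query = {qi: [] for qi, _ in per_query_parts}
        for (qi, _), chains in zip(tasks, results):
            by_query[qi].extend(chains)
        # marking + extension, per query, in input order
        for qi, _ in per_query_parts:
            chains = sort_chains(by_query[qi])
            if not chains:
                continue
            flags = mark_primary_fast(chains, mask_level=config.mask_level)
            for c, f in zip(chains, flags):
                c.flag = f
            secondaries = [c for c in chains if c.flag == ChainFlag.SECONDARY]
            if config.no_secondary:
                chains = [c for c in chains if c.flag == ChainFlag.PRIMARY]
            for c in chains:
                rec = extend_chain(
                    c, queries[qi], ref[c.seqid], config.align_params
                )
                if c.flag == ChainFlag.SECONDARY:
                    rec.mapq = 0
                else:
                    rec.mapq = compute_mapq(
                        c.score, _best_secondary(c, secondaries, config.mask_level)
                    )
                records.append(rec)
    _log(config, f"pipeline done in {time.perf_counter() - t0:.2f}s")
    return records


def align_genomes(ref_path, query_path, config: RunConfig) -> List[PafRecord]:
    """Read both FASTA files and run the pipeline; records in query order."""
    ref = read_fasta(ref_path)
    queries = read_fasta(query_path)
    return align_records(ref, queries, config)
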