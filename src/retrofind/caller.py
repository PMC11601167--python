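"""End-to-end calling pipeline.

Composes the five stages: scan the alignment for insertion/clip
evidence, DBSCAN-cluster the breakpoints, realign each cluster's
candidate sequences to the TE library (one batched aligner invocation),
apply the support and match-length filters, refine passing clusters to
consensus calls with genotypes, and write a VCF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional

import pysam

from .classify import (
    align_to_te_library,
    collect_candidate_sequences,
    filter_and_assign,
    load_family_map,
)
from .cluster import CandidateCluster, build_clusters
from .evidence import ScanStats, scan_alignments
from .params import Parameters
from .refine import TECall, local_depth, make_call
from .vcfout import write_vcf

logger = logging.getLogger("retrofind")


@dataclass
class CallResult:
    calls: list[TECall]
    vcf_path: Optional[str]
    scan_stats: ScanStats
    n_clusters: int
    n_passing: int


def call_sample(
    alignment_path: str,
    te_fasta: str,
    out_vcf: str | None,
    params: Parameters | None = None,
    reference: str | None = None,
    sample_name: str = "SAMPLE",
    region: str | None = None,
    engine: str = "auto",
    family_map_path: str | None = None,
) -> CallResult:
    """Run the full TE-insertion calling pipeline on one sample.

    ``out_vcf`` of ``None`` skips serialisation (library use).  Returns
    the calls plus per-stage counters.  Deterministic for fixed inputs
    and settings.
    """
    params = params or Parameters()
    family_map = load_family_map(family_map_path) if family_map_path else None

    stats = ScanStats()
    evidence = list(
        scan_alignments(
            alignment_path, params, region=region, reference=reference, stats=stats
        )
    )
    logger.info("evidence: %d items from %d reads", len(evidence), stats.reads_used)

    clusters = build_clusters(evidence, params)
    logger.info("clusters: %d candidate loci", len(clusters))

    # one batched aligner invocation over all clusters' candidates
    batched: list[tuple[str, str]] = []
    owner: dict[str, int] = {}
    for cluster in clusters:
        for cand in collect_candidate_sequences(cluster):
            key = f"c{cluster.id}|{cand.id}"
            batched.append((key, cand.sequence))
            owner[key] = cluster.id
    matches = align_to_te_library(batched, te_fasta, engine=engine)
    per_cluster: dict[int, list] = {}
    for m in matches:
        cid = owner[m.read_id]
        prefix = f"c{cid}|"
        per_cluster.setdefault(cid, []).append(
            type(m)(
                read_id=m.read_id[len(prefix):],
                te_name=m.te_name,
                aligned_len=m.aligned_len,
                strand=m.strand,
                query_len=m.query_len,
            )
        )

    calls: list[TECall] = []
    depths: dict[int, int] = {}
    with pysam.AlignmentFile(alignment_path, reference_filename=reference) as af:
        contigs: Mapping[str, int] = dict(zip(af.references, af.lengths))
        for cluster in clusters:
            assignment = filter_and_assign(
                cluster, per_cluster.get(cluster.id, []), params, family_map
            )
            if assignment is None:
                continue
            family, supporting = assignment
            from .refine import consensus_position

            pos = consensus_position(cluster, supporting)
            depth = local_depth(af, cluster.contig, pos, params)
            calls.append(make_call(cluster, family, supporting, depth, params))
            depths[cluster.id] = depth
    calls.sort(key=lambda c: (c.contig, c.position))
    logger.info("calls: %d passing clusters", len(calls))

    vcf_path = None
    if out_vcf is not None:
        vcf_path = write_vcf(
            calls, contigs, sample_name, out_vcf, reference=reference, depths=depths
        )
    return CallResult(
        calls=calls,
        vcf_path=vcf_path,
        scan_stats=stats,
        n_clusters=len(clusters),
        n_passing=len(calls),
    )
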