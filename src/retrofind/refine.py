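"""Consensus breakpoint, insert length and haplotype-aware genotype.

A passing cluster is collapsed to a single call: the consensus position
is the (lower) median of the supporting breakpoints — robust to the odd
stray clip — and the insert length is the median supporting sequence
length.  Genotyping tallies read phasing tags (HP/PS) when the input BAM
is haplotagged: an insertion seen on only one haplotype is reported as a
phased heterozygote on that haplotype, support on both haplotypes means
both chromosomes carry it (homozygous).  Without tags the call defaults
to an unphased heterozygote, upgraded to homozygous when the supporting
reads account for >= ``hom_allele_fraction`` of the local depth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import pysam

from .classify import CandidateSeq, collect_candidate_sequences
from .cluster import CandidateCluster
from .evidence import InsertionEvidence, read_passes_filters
from .params import Parameters


class HaplotypeSupport(NamedTuple):
    hap1: int
    hap2: int
    unphased: int


@dataclass
class TECall:
    """One final TE insertion call."""

    contig: str
    position: int  # 0-based consensus breakpoint
    family: str
    supporting_reads: int
    insert_len: int
    genotype: str
    haplotype_support: HaplotypeSupport
    cluster_id: int
    phase_set: Optional[int] = None


def _supporting_members(
    cluster: CandidateCluster, supporting: Sequence[str]
) -> list[InsertionEvidence]:
    by_id = {c.id: c.evidence for c in collect_candidate_sequences(cluster)}
    wanted = set(supporting)
    return [ev for cid, ev in by_id.items() if cid in wanted]


def _lower_median(values: Sequence[int]) -> int:
    ordered = sorted(values)
    return ordered[(len(ordered) - 1) // 2]


def consensus_position(cluster: CandidateCluster, supporting: Sequence[str]) -> int:
    """Lower median of the supporting members' breakpoint positions."""
    members = _supporting_members(cluster, supporting)
    if not members:
        raise ValueError("supporting read list is empty")
    return _lower_median([m.position for m in members])


def genotype_call(
    cluster: CandidateCluster,
    supporting: Sequence[str],
    local_depth: int,
    params: Parameters | None = None,
) -> tuple[str, HaplotypeSupport]:
    """Haplotype-aware genotype for one call.

    See module docstring for the decision rule.  ``local_depth`` of 0
    yields ``./.`` (unknown) while the call itself is retained.
    """
    params = params or Parameters()
    members = _supporting_members(cluster, supporting)
    hap1 = sum(1 for m in members if m.haplotype == 1)
    hap2 = sum(1 for m in members if m.haplotype == 2)
    unphased = len(members) - hap1 - hap2
    support = HaplotypeSupport(hap1, hap2, unphased)

    tagged = hap1 + hap2
    if tagged > 0:
        if hap1 / tagged >= params.haplotype_purity:
            return "1|0", support
        if hap2 / tagged >= params.haplotype_purity:
            return "0|1", support
        return "1/1", support
    if local_depth == 0:
        return "./.", support
    if len(members) / local_depth >= params.hom_allele_fraction:
        return "1/1", support
    return "0/1", support


def local_depth(
    alignment: pysam.AlignmentFile, contig: str, position: int, params: Parameters
) -> int:
    """Count MAPQ-passing primary reads overlapping ``position``."""
    pos = max(0, position)
    return alignment.count(
        contig,
        pos,
        pos + 1,
        read_callback=lambda r: read_passes_filters(r, params),
    )


def make_call(
    cluster: CandidateCluster,
    family: str,
    supporting: Sequence[str],
    depth: int,
    params: Parameters,
) -> TECall:
    members = _supporting_members(cluster, supporting)
    position = consensus_position(cluster, supporting)
    genotype, hap_support = genotype_call(cluster, supporting, depth, params)
    insert_len = _lower_median([m.length for m in members])
    phase_sets = [m.phase_set for m in members if m.phase_set is not None]
    phase_set = _lower_median(phase_sets) if (phase_sets and "|" in genotype) else None
    return TECall(
        contig=cluster.contig,
        position=position,
        family=family,
        supporting_reads=len(members),
        insert_len=insert_len,
        genotype=genotype,
        haplotype_support=hap_support,
        cluster_id=cluster.id,
        phase_set=phase_set,
    )
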