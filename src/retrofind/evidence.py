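"""Read-level insertion evidence from long-read alignments.

A non-reference insertion leaves two footprints in a BAM/CRAM: reads that
span the event carry a CIGAR ``I`` operation holding the inserted bases,
and reads whose alignment ends inside the event are soft-clipped with the
insertion sequence in the clipped tail.  Both are collected here as
:class:`InsertionEvidence`, the currency of the downstream clustering and
classification stages.

Supplementary and secondary alignments are ignored: the sequence needed
for TE classification lives in the soft-clipped bases of the primary
alignment.  Hard clips carry no sequence and are only counted.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import pysam

from .params import Parameters

# BAM CIGAR operation codes
_CMATCH, _CINS, _CDEL, _CREF_SKIP, _CSOFT, _CHARD = 0, 1, 2, 3, 4, 5
_CEQUAL, _CDIFF = 7, 8
_QUERY_CONSUMING = {_CMATCH, _CINS, _CSOFT, _CEQUAL, _CDIFF}
_REF_CONSUMING = {_CMATCH, _CDEL, _CREF_SKIP, _CEQUAL, _CDIFF}


class EvidenceKind(str, enum.Enum):
    INSERTION_OP = "insertion_op"
    LEFT_CLIP = "left_clip"
    RIGHT_CLIP = "right_clip"


@dataclass(frozen=True)
class InsertionEvidence:
    """One read-level insertion signal.

    ``position`` is the 0-based reference coordinate of the breakpoint:
    for an insertion operation the first reference base to its right, for
    a left clip the read's reference start and for a right clip the
    read's reference end.
    """

    read_id: str
    contig: str
    position: int
    kind: EvidenceKind
    sequence: str
    haplotype: Optional[int] = None
    phase_set: Optional[int] = None

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class ScanStats:
    """Counters accumulated while scanning an alignment file."""

    reads_seen: int = 0
    reads_used: int = 0
    reads_filtered: int = 0
    skipped_no_sequence: int = 0
    hard_clips: int = 0
    evidence: int = 0


def _phasing_tags(read: pysam.AlignedSegment) -> tuple[Optional[int], Optional[int]]:
    hp = read.get_tag("HP") if read.has_tag("HP") else None
    ps = read.get_tag("PS") if read.has_tag("PS") else None
    return (int(hp) if hp is not None else None,
            int(ps) if ps is not None else None)


def extract_insertion_ops(
    read: pysam.AlignedSegment,
    params: Parameters,
    stats: ScanStats | None = None,
) -> list[InsertionEvidence]:
    """Emit one evidence item per CIGAR ``I`` op of length >= min_insertion_len."""
    seq = read.query_sequence
    if seq is None:
        if stats is not None:
            stats.skipped_no_sequence += 1
        return []
    hp, ps = _phasing_tags(read)
    out: list[InsertionEvidence] = []
    qpos = 0
    rpos = read.reference_start
    for op, length in read.cigartuples or []:
        if op == _CINS and length >= params.min_insertion_len:
            out.append(
                InsertionEvidence(
                    read_id=read.query_name,
                    contig=read.reference_name,
                    position=rpos,
                    kind=EvidenceKind.INSERTION_OP,
                    sequence=seq[qpos : qpos + length],
                    haplotype=hp,
                    phase_set=ps,
                )
            )
        if op in _QUERY_CONSUMING:
            qpos += length
        if op in _REF_CONSUMING:
            rpos += length
    return out


def extract_clip_events(
    read: pysam.AlignedSegment,
    params: Parameters,
    stats: ScanStats | None = None,
) -> list[InsertionEvidence]:
    """Emit evidence for terminal soft clips of length >= min_clip_len.

    Hard clips carry no bases; they only increment ``stats.hard_clips``.
    """
    cigar = read.cigartuples
    if not cigar:
        return []
    seq = read.query_sequence
    if seq is None:
        if stats is not None:
            stats.skipped_no_sequence += 1
        return []
    hp, ps = _phasing_tags(read)
    out: list[InsertionEvidence] = []
    first_op, first_len = cigar[0]
    last_op, last_len = cigar[-1]
    if first_op == _CHARD or last_op == _CHARD:
        if stats is not None:
            stats.hard_clips += 1
    if first_op == _CSOFT and first_len >= params.min_clip_len:
        out.append(
            InsertionEvidence(
                read_id=read.query_name,
                contig=read.reference_name,
                position=read.reference_start,
                kind=EvidenceKind.LEFT_CLIP,
                sequence=seq[:first_len],
                haplotype=hp,
                phase_set=ps,
            )
        )
    if last_op == _CSOFT and last_len >= params.min_clip_len and len(cigar) > 1:
        out.append(
            InsertionEvidence(
                read_id=read.query_name,
                contig=read.reference_name,
                position=read.reference_end,
                kind=EvidenceKind.RIGHT_CLIP,
                sequence=seq[len(seq) - last_len :],
                haplotype=hp,
                phase_set=ps,
            )
        )
    return out


def read_passes_filters(read: pysam.AlignedSegment, params: Parameters) -> bool:
    return (
        not read.is_unmapped
        and not read.is_secondary
        and not read.is_supplementary
        and not read.is_duplicate
        and not read.is_qcfail
        and read.mapping_quality >= params.min_mapq
    )


def _read_evidence(
    read: pysam.AlignedSegment, params: Parameters, stats: ScanStats
) -> list[InsertionEvidence]:
    return extract_insertion_ops(read, params, stats) + extract_clip_events(
        read, params, stats
    )


def scan_alignments(
    alignment_path: str,
    params: Parameters,
    region: str | None = None,
    reference: str | None = None,
    stats: ScanStats | None = None,
) -> Iterator[InsertionEvidence]:
    """Stream insertion and clip evidence from a sorted, indexed BAM/CRAM.

    Evidence is yielded in nondecreasing position order per contig.
    ``region`` is a samtools-style region string restricting the scan;
    ``reference`` is required for CRAM decoding.

    Raises
    ------
    FileNotFoundError
        If the alignment index is missing.
    ValueError
        If ``region`` names a contig absent from the header.
    """
    stats = stats if stats is not None else ScanStats()
    with pysam.AlignmentFile(
        alignment_path, reference_filename=reference
    ) as af:
        try:
            has_index = af.check_index()
        except (ValueError, AttributeError):
            has_index = False
        if not has_index:
            raise FileNotFoundError(
                f"{alignment_path} has no index; run 'samtools index' first"
            )
        if region is not None:
            contig = region.split(":")[0]
            if contig not in af.references:
                raise ValueError(f"region contig {contig!r} not in alignment header")
            iterators: Iterable[tuple[str, Iterable[pysam.AlignedSegment]]] = [
                (contig, af.fetch(region=region))
            ]
        else:
            iterators = [(c, af.fetch(c)) for c in af.references]
        for _contig, reads in iterators:
            buffered: list[InsertionEvidence] = []
            for read in reads:
                stats.reads_seen += 1
                if not read_passes_filters(read, params):
                    stats.reads_filtered += 1
                    continue
                stats.reads_used += 1
                buffered.extend(_read_evidence(read, params, stats))
            buffered.sort(key=lambda ev: (ev.position, ev.read_id, ev.kind.value))
            stats.evidence += len(buffered)
            yield from buffered
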