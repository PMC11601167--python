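"""Shared fixtures: programmatic BAM/FASTA builders and small simulations."""

from __future__ import annotations

import numpy as np
import pysam
import pytest

from retrofind.params import Parameters

CONTIG = "chr1"
CONTIG_LEN = 100_000


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), n))


def query_length(cigar: str) -> int:
    """Query bases consumed by a CIGAR string (M/I/S/=/X)."""
    total = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            if ch in "MIS=X":
                total += int(num)
            num = ""
    return total


@pytest.fixture
def bam_header() -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": CONTIG, "LN": CONTIG_LEN}]}
    )


@pytest.fixture
def make_read(bam_header):
    """Factory for in-memory aligned reads with a given CIGAR."""
    rng = np.random.default_rng(7)

    def _make(
        cigar: str,
        start: int = 1000,
        name: str = "read1",
        mapq: int = 60,
        seq: str | None = None,
        tags: dict | None = None,
        flag: int = 0,
    ) -> pysam.AlignedSegment:
        read = pysam.AlignedSegment(bam_header)
        read.query_name = name
        read.reference_id = 0
        read.reference_start = start
        read.mapping_quality = mapq
        read.cigarstring = cigar
        read.flag = flag
        qlen = query_length(cigar)
        read.query_sequence = seq if seq is not None else _random_seq(rng, qlen)
        if tags:
            read.set_tags(list(tags.items()))
        return read

    return _make


@pytest.fixture
def make_bam(tmp_path, bam_header, make_read):
    """Write a sorted, indexed BAM from (cigar, start, kwargs) specs."""

    def _make(reads: list[dict], path_name: str = "fixture.bam") -> str:
        unsorted = tmp_path / ("unsorted_" + path_name)
        out = tmp_path / path_name
        with pysam.AlignmentFile(unsorted, "wb", header=bam_header) as bam:
            for i, spec in enumerate(reads):
                spec = dict(spec)
                spec.setdefault("name", f"read{i}")
                bam.write(make_read(**spec))
        pysam.sort("-o", str(out), str(unsorted))
        pysam.index(str(out))
        return str(out)

    return _make


@pytest.fixture
def default_params() -> Parameters:
    return Parameters()


@pytest.fixture
def te_library_fasta(tmp_path) -> str:
    """A small synthetic 4-family TE consensus FASTA."""
    from retrofind.simulate import make_te_library

    path = tmp_path / "te_library.fasta"
    return make_te_library(str(path), seed=11)
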