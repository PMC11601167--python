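"""VCF 4.2 serialisation of TE insertion calls.

Calls are written as symbolic mobile-element insertions
(``<INS:ME:FAMILY>``) with SVTYPE/SVLEN/END/TEFAMILY/SUPPORT INFO fields
and a per-sample ``GT:DP:HS`` FORMAT (HS = supporting reads on haplotype
1, haplotype 2 and unphased).  The genotype is written phased (``|``)
only when it was resolved from read haplotype tags.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import pysam

from . import __version__
from .refine import TECall


def _header(
    contigs: Mapping[str, int], families: Sequence[str], sample_name: str
) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line(f"##source=retrofind-{__version__}")
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.info.add("SVTYPE", 1, "String", "Type of structural variant")
    header.info.add("SVLEN", 1, "Integer", "Median length of the inserted sequence")
    header.info.add("END", 1, "Integer", "End position of the variant")
    header.info.add("TEFAMILY", 1, "String", "Transposable element family of the insertion")
    header.info.add("SUPPORT", 1, "Integer", "Number of supporting reads")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth at the breakpoint")
    header.formats.add(
        "HS", 3, "Integer", "Supporting reads on haplotype 1, haplotype 2, unphased"
    )
    for family in sorted({f.upper() for f in families}):
        header.add_line(
            f"##ALT=<ID=INS:ME:{family},Description="
            f'"Insertion of a {family} mobile element">'
        )
    header.add_sample(sample_name)
    return header


_GT = {
    "1|0": ((1, 0), True),
    "0|1": ((0, 1), True),
    "1/1": ((1, 1), False),
    "0/1": ((0, 1), False),
    "./.": ((None, None), False),
}


def write_vcf(
    calls: Sequence[TECall],
    contigs: Mapping[str, int],
    sample_name: str,
    out: str,
    reference: str | None = None,
    depths: Mapping[int, int] | None = None,
) -> str:
    """Write calls to ``out`` as VCF 4.2 and return the path.

    ``contigs`` maps contig name to length (used for the header and for
    validating calls).  ``reference`` is an optional FASTA used to fill
    the REF base; without it REF is ``N``.  ``depths`` optionally maps
    ``cluster_id`` to breakpoint depth for the DP field.  Calls must be
    sorted by (contig, position); unsorted input or a call on an unknown
    contig is fatal.
    """
    order = [(c.contig, c.position) for c in calls]
    if order != sorted(order):
        raise ValueError("calls must be sorted by (contig, position)")
    for call in calls:
        if call.contig not in contigs:
            raise ValueError(f"call on unknown contig {call.contig!r}")

    fasta = pysam.FastaFile(reference) if reference else None
    header = _header(contigs, [c.family for c in calls], sample_name)
    try:
        with pysam.VariantFile(str(out), "w", header=header) as vcf:
            for call in calls:
                ref_base = "N"
                if fasta is not None and call.contig in fasta.references:
                    base = fasta.fetch(call.contig, call.position, call.position + 1)
                    ref_base = base.upper() or "N"
                rec = vcf.new_record(
                    contig=call.contig,
                    start=call.position,
                    stop=call.position + 1,
                    alleles=(ref_base, f"<INS:ME:{call.family.upper()}>"),
                )
                rec.id = f"retrofind_{call.cluster_id}"
                rec.info["SVTYPE"] = "INS"
                rec.info["SVLEN"] = call.insert_len
                rec.info["TEFAMILY"] = call.family
                rec.info["SUPPORT"] = call.supporting_reads
                alleles, phased = _GT[call.genotype]
                sample = rec.samples[sample_name]
                sample["GT"] = alleles
                sample.phased = phased
                if depths is not None and call.cluster_id in depths:
                    sample["DP"] = depths[call.cluster_id]
                sample["HS"] = tuple(call.haplotype_support)
                vcf.write(rec)
    finally:
        if fasta is not None:
            fasta.close()
    return str(out)


def read_vcf_calls(path: str) -> list[dict]:
    """Parse a retrofind VCF back into plain per-record dictionaries.

    Used by the evaluator and for round-trip checks; positions are
    returned 0-based to match the internal convention.
    """
    out: list[dict] = []
    with pysam.VariantFile(str(path)) as vcf:
        sample_names = list(vcf.header.samples)
        for rec in vcf:
            family = rec.info.get("TEFAMILY")
            if family is None:
                alt = rec.alts[0] if rec.alts else ""
                family = alt.strip("<>").split(":")[-1] if "INS:ME" in alt else None
            entry = {
                "contig": rec.contig,
                "position": rec.start,
                "family": family,
                "svlen": rec.info.get("SVLEN"),
                "support": rec.info.get("SUPPORT"),
            }
            if sample_names:
                sample = rec.samples[sample_names[0]]
                gt = sample.get("GT")
                sep = "|" if sample.phased else "/"
                entry["genotype"] = (
                    sep.join("." if a is None else str(a) for a in gt)
                    if gt is not None
                    else "./."
                )
                entry["hs"] = tuple(sample.get("HS") or ())
            out.append(entry)
    return out
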