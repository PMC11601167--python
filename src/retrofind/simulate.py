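"""Synthetic benchmark: a diploid genome with planted TE insertions and
long noisy reads with a known truth set.

The generator emulates the standard simulation design for evaluating TE
insertion callers: take a TE-free background genome, plant full-length
copies of TE consensus sequences (Alu, L1, SVA, HERV) at random,
well-spaced positions on one or both haplotypes, and sequence the two
haplotypes with long reads at ~20x combined coverage and PacBio-RS-II-like
error rates (~6% mismatch, 3% insertion, 3% deletion).

Reads can be emitted as FASTQ for a real aligner, or in *direct-BAM*
mode, where each read's true alignment to the un-inserted reference is
written with the correct CIGAR — planted insertions appear as ``I``
operations, reads ending inside an insertion appear soft-clipped — so
the caller can be exercised hermetically without an external aligner.

All sequences here (background genome and TE "consensus" entries) are
seeded random synthetic sequences; the TE library carries real family
names and realistic lengths but no real TE sequence content.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pysam

# Approximate full-length sizes (bp) of the four retroelement families.
TE_FAMILY_LENGTHS: dict[str, int] = {
    "Alu": 300,
    "SVA": 1800,
    "L1": 6000,
    "HERV": 9500,
}

DEFAULT_INSERTION_COUNTS: dict[str, int] = {
    "Alu": 60,
    "L1": 60,
    "HERV": 30,
    "SVA": 30,
}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i


@dataclass
class SimConfig:
    """Study conditions for the synthetic benchmark."""

    genome_len: int = 5_000_000
    n_insertions: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_INSERTION_COUNTS)
    )
    coverage: float = 20.0
    error_rates: tuple[float, float, float] = (0.06, 0.03, 0.03)  # mismatch, ins, del
    read_len: tuple[float, float] = (12_000.0, 3_000.0)  # mean, sd
    min_read_len: int = 1_000
    seed: int = 0
    het_fraction: float = 0.0
    min_spacing: int = 1_000
    phase_tags: bool = True
    contig: str = "chr1"

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        for rate in self.error_rates:
            if not (0 <= rate <= 0.2):
                raise ValueError("error rates must be in [0, 0.2]")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one planted insertion (position on the
    un-inserted reference)."""

    contig: str
    position: int
    family: str
    inserted_len: int
    zygosity: str  # "het" or "hom"
    haplotype: int = 0  # 1 or 2 for het; 0 = both


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, n)]


def _to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def write_fasta(records: Mapping[str, str], path: str, width: int = 80) -> str:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    return str(path)


def make_te_library(path: str, seed: int = 0,
                    lengths: Mapping[str, int] | None = None) -> str:
    """Write a synthetic TE consensus FASTA (one entry per family).

    Sequences are seeded random DNA at the family's full length; they
    stand in for real consensus sequences so the benchmark is
    self-contained.
    """
    lengths = dict(lengths or TE_FAMILY_LENGTHS)
    rng = np.random.default_rng([seed, 101])
    records = {name: _to_str(_random_seq(rng, n)) for name, n in lengths.items()}
    return write_fasta(records, path)


def make_genome(cfg: SimConfig) -> str:
    """Seeded random A/C/G/T background sequence with no TE homology."""
    return _to_str(_random_seq(_rng(cfg, 0), cfg.genome_len))


def _draw_positions(
    rng: np.random.Generator, n: int, genome_len: int, min_spacing: int
) -> list[int]:
    lo, hi = min_spacing, genome_len - min_spacing
    if hi <= lo or n * 2 * min_spacing > genome_len:
        raise ValueError("requested insertion density is infeasible for this genome")
    accepted: list[int] = []
    attempts = 0
    from bisect import bisect_left, insort

    while len(accepted) < n:
        attempts += 1
        if attempts > 10_000 * max(n, 1):
            raise ValueError("could not place insertions with the required spacing")
        p = int(rng.integers(lo, hi))
        i = bisect_left(accepted, p)
        if i > 0 and p - accepted[i - 1] < min_spacing:
            continue
        if i < len(accepted) and accepted[i] - p < min_spacing:
            continue
        insort(accepted, p)
    return accepted


@dataclass
class _HaplotypeMap:
    """Piecewise map between one haplotype's coordinates and the reference.

    ``bounds`` is the flat sorted array [hs0, he0, hs1, he1, ...] of
    planted-insertion intervals in haplotype coordinates; ``cum_ins[k]``
    is the total inserted length in intervals 0..k-1.
    """

    bounds: np.ndarray
    cum_ins: np.ndarray

    def interval_index(self, h: np.ndarray) -> np.ndarray:
        return np.searchsorted(self.bounds, h, side="right")

    def in_insertion(self, h: np.ndarray) -> np.ndarray:
        return self.interval_index(h) % 2 == 1

    def to_reference(self, h: int) -> int:
        idx = int(np.searchsorted(self.bounds, h, side="right"))
        if idx % 2 == 1:
            raise ValueError("haplotype position lies inside a planted insertion")
        return h - int(self.cum_ins[idx // 2])


def plant_insertions(
    genome: str, te_library: Mapping[str, str], cfg: SimConfig
) -> tuple[tuple[str, str], list[TruthRecord], tuple[_HaplotypeMap, _HaplotypeMap]]:
    """Plant TE copies into the genome, producing two haplotype sequences.

    Positions are uniform-random with >= ``min_spacing`` bp between
    events and from the contig ends.  Homozygous events go on both
    haplotypes, heterozygous events on one randomly chosen haplotype.
    Returns the haplotype sequences, the truth records and the
    haplotype-to-reference coordinate maps used by direct-BAM mode.
    """
    rng = _rng(cfg, 1)
    families: list[str] = []
    for family in sorted(cfg.n_insertions):
        count = cfg.n_insertions[family]
        if family not in te_library:
            raise KeyError(f"family {family!r} missing from the TE library")
        families.extend([family] * count)
    n = len(families)
    if n == 0:
        empty = _HaplotypeMap(np.empty(0, dtype=np.int64), np.zeros(1, dtype=np.int64))
        return (genome, genome), [], (empty, empty)

    positions = _draw_positions(rng, n, cfg.genome_len, cfg.min_spacing)
    shuffled = [families[i] for i in rng.permutation(n)]
    truths: list[TruthRecord] = []
    for pos, family in zip(positions, shuffled):
        het = bool(rng.random() < cfg.het_fraction)
        hap = int(rng.integers(1, 3)) if het else 0
        truths.append(
            TruthRecord(
                contig=cfg.contig,
                position=pos,
                family=family,
                inserted_len=len(te_library[family]),
                zygosity="het" if het else "hom",
                haplotype=hap,
            )
        )

    genome_arr = np.frombuffer(genome.encode("ascii"), dtype=np.uint8)
    haplotypes: list[str] = []
    maps: list[_HaplotypeMap] = []
    for hap_id in (1, 2):
        segments: list[np.ndarray] = []
        bounds: list[int] = []
        cum = [0]
        prev = 0
        offset = 0
        for t in truths:
            if t.haplotype not in (0, hap_id):
                continue
            te_arr = np.frombuffer(
                te_library[t.family].upper().encode("ascii"), dtype=np.uint8
            )
            segments.append(genome_arr[prev : t.position])
            segments.append(te_arr)
            hstart = t.position + offset
            bounds.extend([hstart, hstart + len(te_arr)])
            offset += len(te_arr)
            cum.append(offset)
            prev = t.position
        segments.append(genome_arr[prev:])
        haplotypes.append(_to_str(np.concatenate(segments)))
        maps.append(
            _HaplotypeMap(np.asarray(bounds, dtype=np.int64),
                          np.asarray(cum, dtype=np.int64))
        )
    return (haplotypes[0], haplotypes[1]), truths, (maps[0], maps[1])


def _simulate_one_read(
    hap_arr: np.ndarray, rng: np.random.Generator, cfg: SimConfig
) -> tuple[int, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Draw one read: (start, template_len arrays) with per-base error masks.

    Returns (start, query_bases_per_template (with substitutions),
    is_del, is_ins, inserted_bases).
    """
    mean, sd = cfg.read_len
    length = int(np.clip(rng.normal(mean, sd), cfg.min_read_len, None))
    length = min(length, len(hap_arr))
    start = int(rng.integers(0, len(hap_arr) - length + 1))
    template = hap_arr[start : start + length]

    pm, pi, pd = cfg.error_rates
    u = rng.random(length)
    is_mm = u < pm
    is_ins = (u >= pm) & (u < pm + pi)
    is_del = (u >= pm + pi) & (u < pm + pi + pd)

    bases = template.copy()
    n_mm = int(is_mm.sum())
    if n_mm:
        idx = _BASE_INDEX[template[is_mm]].astype(np.int64)
        bases[is_mm] = _BASES[(idx + rng.integers(1, 4, n_mm)) % 4]
    inserted = _random_seq(rng, int(is_ins.sum()))
    return start, bases, is_del, is_ins, inserted


def _rle(codes: np.ndarray) -> list[tuple[int, int]]:
    if len(codes) == 0:
        return []
    change = np.nonzero(np.diff(codes))[0] + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(codes)]))
    return [(int(codes[s]), int(e - s)) for s, e in zip(starts, ends)]


_OP_M, _OP_I, _OP_D, _OP_NONE = 0, 1, 2, 3


def _project_read(
    start: int,
    bases: np.ndarray,
    is_del: np.ndarray,
    is_ins: np.ndarray,
    inserted: np.ndarray,
    hmap: _HaplotypeMap,
) -> tuple[int, list[tuple[int, int]], np.ndarray] | None:
    """True alignment of one simulated read to the un-inserted reference.

    Returns (reference_start, cigartuples, query_sequence) or ``None``
    for a read with no reference-aligned base (entirely inside a planted
    insertion).  Planted bases become I ops; error deletions become D
    (dropped inside planted regions); leading/trailing unaligned bases
    become soft clips.
    """
    length = len(bases)
    h = start + np.arange(length, dtype=np.int64)
    planted = hmap.in_insertion(h)

    base_code = np.full(length, _OP_M, dtype=np.int8)
    base_code[planted] = _OP_I
    base_code[is_del & ~planted] = _OP_D
    base_code[is_del & planted] = _OP_NONE

    # interleave per-base codes with error-insertion I slots
    stream = np.full(2 * length, _OP_NONE, dtype=np.int8)
    stream[0::2] = base_code
    stream[1::2] = np.where(is_ins, _OP_I, _OP_NONE)
    stream = stream[stream != _OP_NONE]

    m_positions = np.nonzero(base_code == _OP_M)[0]
    if len(m_positions) == 0:
        return None
    ref_start = hmap.to_reference(start + int(m_positions[0]))

    # assemble the query: kept template bases with inserted bases spliced in
    keep = ~is_del
    kept = bases[keep]
    if len(inserted):
        kept_index = np.cumsum(keep) - 1  # query index of each template base
        ins_at = kept_index[is_ins] + 1
        kept = np.insert(kept, ins_at, inserted)
    query = kept

    ops = _rle(stream)
    # trim: before the first M run, I becomes soft clip and D is dropped
    first_m = next(i for i, (op, _) in enumerate(ops) if op == _OP_M)
    last_m = max(i for i, (op, _) in enumerate(ops) if op == _OP_M)
    lead_clip = sum(n for op, n in ops[:first_m] if op == _OP_I)
    tail_clip = sum(n for op, n in ops[last_m + 1 :] if op == _OP_I)
    cigar = ops[first_m : last_m + 1]
    if lead_clip:
        cigar = [(4, lead_clip)] + cigar
    if tail_clip:
        cigar = cigar + [(4, tail_clip)]
    return ref_start, cigar, query


def simulate_reads(
    haplotypes: tuple[str, str],
    maps: tuple[_HaplotypeMap, _HaplotypeMap],
    cfg: SimConfig,
    fastq_out: str | None = None,
    bam_out: str | None = None,
) -> dict:
    """Simulate reads from both haplotypes to the target coverage.

    ``fastq_out`` writes reads (reverse-strand reads reverse-complemented)
    for an external aligner.  ``bam_out`` writes the direct-BAM truth
    alignment (coordinate-sorted and indexed).  Either or both may be
    given.  Returns summary counters.
    """
    if fastq_out is None and bam_out is None:
        raise ValueError("at least one of fastq_out/bam_out is required")
    rng = _rng(cfg, 2)
    hap_arrs = [
        np.frombuffer(h.encode("ascii"), dtype=np.uint8) for h in haplotypes
    ]
    target_per_hap = cfg.coverage / 2.0 * cfg.genome_len

    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": cfg.contig, "LN": cfg.genome_len}],
            "PG": [{"ID": "retrofind-sim", "PN": "retrofind-sim"}],
        }
    )
    stats = {"reads": 0, "bases": 0, "unmapped_dropped": 0}
    fastq = open(fastq_out, "w") if fastq_out else None
    tmp_bam = None
    bam = None
    if bam_out:
        tmp_dir = tempfile.mkdtemp(prefix="retrofind_sim_")
        tmp_bam = str(Path(tmp_dir) / "unsorted.bam")
        bam = pysam.AlignmentFile(tmp_bam, "wb", header=header)
    try:
        read_idx = 0
        for hap_id, (hap_arr, hmap) in enumerate(zip(hap_arrs, maps), start=1):
            bases_done = 0
            while bases_done < target_per_hap:
                start, bases, is_del, is_ins, inserted = _simulate_one_read(
                    hap_arr, rng, cfg
                )
                reverse = bool(rng.random() < 0.5)
                read_idx += 1
                name = f"r{read_idx}_h{hap_id}"
                projected = _project_read(start, bases, is_del, is_ins, inserted, hmap)
                if projected is None:
                    query = bases[~is_del]
                    if len(inserted):
                        kept_index = np.cumsum(~is_del) - 1
                        query = np.insert(query, kept_index[is_ins] + 1, inserted)
                    seq = _to_str(query)
                    stats["unmapped_dropped"] += 1
                else:
                    ref_start, cigar, query = projected
                    seq = _to_str(query)
                    if bam is not None:
                        a = pysam.AlignedSegment(header)
                        a.query_name = name
                        a.query_sequence = seq
                        a.flag = 16 if reverse else 0
                        a.reference_id = 0
                        a.reference_start = ref_start
                        a.mapping_quality = 60
                        a.cigartuples = cigar
                        if cfg.phase_tags:
                            a.set_tags([("HP", hap_id), ("PS", 1)])
                        bam.write(a)
                if fastq is not None:
                    out_seq = _revcomp_str(seq) if reverse else seq
                    # SAM-style comment tags; minimap2 -y copies them to the BAM
                    comment = f"\tHP:i:{hap_id}\tPS:i:1" if cfg.phase_tags else ""
                    fastq.write(f"@{name}{comment}\n{out_seq}\n+\n{'I' * len(out_seq)}\n")
                stats["reads"] += 1
                stats["bases"] += len(seq)
                bases_done += len(bases)
    finally:
        if fastq is not None:
            fastq.close()
        if bam is not None:
            bam.close()
    if bam_out:
        pysam.sort("-o", str(bam_out), tmp_bam)
        pysam.index(str(bam_out))
        shutil.rmtree(Path(tmp_bam).parent, ignore_errors=True)
    return stats


_RC = str.maketrans("ACGTN", "TGCAN")


def _revcomp_str(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def write_truth(truths: Sequence[TruthRecord], path: str) -> str:
    with open(path, "w") as fh:
        fh.write("#contig\tposition\tfamily\tinserted_len\tzygosity\thaplotype\n")
        for t in truths:
            fh.write(
                f"{t.contig}\t{t.position}\t{t.family}\t{t.inserted_len}"
                f"\t{t.zygosity}\t{t.haplotype}\n"
            )
    return str(path)


def read_truth(path: str) -> list[TruthRecord]:
    out: list[TruthRecord] = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        contig, pos, family, ilen, zyg, hap = line.split("\t")
        out.append(
            TruthRecord(contig, int(pos), family, int(ilen), zyg, int(hap))
        )
    return out


def align_with_minimap2(
    fastq: str,
    reference_fasta: str,
    out_bam: str,
    preset: str = "map-pb",
    threads: int = 1,
    minimap2_path: str = "minimap2",
) -> str:
    """Align simulated reads with minimap2 and produce a sorted, indexed BAM."""
    if shutil.which(minimap2_path) is None:
        raise FileNotFoundError("minimap2 not found on PATH")
    with tempfile.TemporaryDirectory(prefix="retrofind_aln_") as tmp:
        sam = Path(tmp) / "aln.sam"
        cmd = [
            minimap2_path, "-a", "-x", preset, "--secondary=no",
            "-t", str(threads), "-y", str(reference_fasta), str(fastq),
        ]
        with sam.open("w") as out:
            proc = subprocess.run(cmd, stdout=out, stderr=subprocess.PIPE, text=True)
        if proc.returncode != 0:
            raise RuntimeError(f"minimap2 failed: {proc.stderr.strip()}")
        pysam.sort("-o", str(out_bam), str(sam))
    pysam.index(str(out_bam))
    return str(out_bam)


def run_simulation(
    out_dir: str,
    cfg: SimConfig,
    te_library_fasta: str | None = None,
    mode: str = "both",
) -> dict:
    """Generate a full benchmark dataset under ``out_dir``.

    Writes reference.fasta, te_library.fasta (unless provided),
    truth.tsv, and reads.bam (direct-BAM) and/or reads.fastq depending
    on ``mode`` ("bam", "fastq" or "both").  Returns a manifest of paths
    plus simulation counters.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if te_library_fasta is None:
        te_library_fasta = str(out / "te_library.fasta")
        make_te_library(te_library_fasta, seed=cfg.seed)
    from .classify import load_te_library

    library = load_te_library(te_library_fasta)
    genome = make_genome(cfg)
    ref_path = write_fasta({cfg.contig: genome}, str(out / "reference.fasta"))
    haplotypes, truths, maps = plant_insertions(genome, library, cfg)
    truth_path = write_truth(truths, str(out / "truth.tsv"))
    fastq_out = str(out / "reads.fastq") if mode in ("fastq", "both") else None
    bam_out = str(out / "reads.bam") if mode in ("bam", "both") else None
    stats = simulate_reads(haplotypes, maps, cfg, fastq_out=fastq_out, bam_out=bam_out)
    return {
        "reference": ref_path,
        "te_library": te_library_fasta,
        "truth": truth_path,
        "fastq": fastq_out,
        "bam": bam_out,
        "stats": stats,
        "n_insertions": len(truths),
    }
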