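"""Classification of candidate insertion sequences against a TE library.

Each cluster's inserted/clipped sequences are realigned to the
user-provided FASTA of TE consensus sequences.  The default engine shells
out to minimap2 (one batched invocation per run, PAF output); a built-in
edlib engine provides a hermetic fallback so the pipeline runs without
external binaries.  A cluster becomes a call only when enough candidates
match the same TE family and each match covers a minimum fraction of its
candidate sequence.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import edlib
import pysam

from .cluster import CandidateCluster
from .evidence import InsertionEvidence
from .params import Parameters

# minimum full-query identity for the edlib fallback to report a hit;
# random sequence scores ~0.5, a TE copy at long-read error rates >0.8
EDLIB_MIN_IDENTITY = 0.7

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TEMatch:
    """Best alignment of one candidate sequence to the TE library."""

    read_id: str
    te_name: str
    aligned_len: int
    strand: str  # "+" or "-"
    query_len: int


@dataclass(frozen=True)
class CandidateSeq:
    """A candidate sequence extracted from a cluster member.

    ``id`` is the read id, suffix-disambiguated (``#2``, ``#3`` ...) when
    one read contributes several evidence items to the same cluster.
    """

    id: str
    read_id: str
    sequence: str
    evidence: InsertionEvidence


def collect_candidate_sequences(cluster: CandidateCluster) -> list[CandidateSeq]:
    """One candidate per cluster member, ordered by read id, ids unique."""
    members = sorted(
        cluster.members, key=lambda m: (m.read_id, m.position, m.kind.value)
    )
    seen: dict[str, int] = {}
    out: list[CandidateSeq] = []
    for m in members:
        n = seen.get(m.read_id, 0) + 1
        seen[m.read_id] = n
        cid = m.read_id if n == 1 else f"{m.read_id}#{n}"
        out.append(CandidateSeq(id=cid, read_id=m.read_id, sequence=m.sequence, evidence=m))
    return out


def load_te_library(te_fasta: str) -> dict[str, str]:
    """Read the TE FASTA into {name: sequence}; empty/unreadable is fatal."""
    try:
        entries: dict[str, str] = {}
        with pysam.FastxFile(str(te_fasta)) as fh:
            for rec in fh:
                entries[rec.name] = rec.sequence.upper()
    except OSError as exc:
        raise ValueError(f"cannot read TE FASTA {te_fasta}: {exc}") from exc
    if not entries:
        raise ValueError(f"TE FASTA {te_fasta} contains no sequences")
    return entries


def load_family_map(path: str) -> dict[str, str]:
    """Two-column TSV mapping TE name -> family (e.g. AluYa5 -> Alu)."""
    mapping: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValueError(f"malformed family-map line: {line!r}")
        mapping[fields[0]] = fields[1]
    return mapping


def _better(a: tuple, b: tuple) -> bool:
    """Compare (score, aligned_len, -lex) keys; True if a beats b."""
    if a[0] != b[0]:
        return a[0] > b[0]
    if a[1] != b[1]:
        return a[1] > b[1]
    return a[2] < b[2]


def _align_minimap2(
    candidates: Sequence[tuple[str, str]],
    te_fasta: str,
    preset: str,
    minimap2_path: str,
) -> list[TEMatch]:
    with tempfile.TemporaryDirectory(prefix="retrofind_mm2_") as tmp:
        query = Path(tmp) / "candidates.fasta"
        with query.open("w") as fh:
            for cid, seq in candidates:
                fh.write(f">{cid}\n{seq}\n")
        cmd = [
            minimap2_path,
            "-x",
            preset,
            "--secondary=no",
            "-t",
            "1",
            str(te_fasta),
            str(query),
        ]
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0:
            raise RuntimeError(
                f"minimap2 failed (exit {proc.returncode}): {proc.stderr.strip()}"
            )
        paf = proc.stdout

    best: dict[str, tuple[tuple, TEMatch]] = {}
    qlens = {cid: len(seq) for cid, seq in candidates}
    for line in paf.splitlines():
        f = line.split("\t")
        if len(f) < 12:
            continue
        qname, strand, tname = f[0], f[4], f[5]
        qstart, qend, matches = int(f[2]), int(f[3]), int(f[9])
        aligned_len = qend - qstart
        key = (matches, aligned_len, tname)
        match = TEMatch(
            read_id=qname,
            te_name=tname,
            aligned_len=aligned_len,
            strand=strand,
            query_len=qlens.get(qname, int(f[1])),
        )
        if qname not in best or _better(key, best[qname][0]):
            best[qname] = (key, match)
    return [best[cid][1] for cid, _ in candidates if cid in best]


def _align_edlib(
    candidates: Sequence[tuple[str, str]],
    library: Mapping[str, str],
    min_identity: float = EDLIB_MIN_IDENTITY,
) -> list[TEMatch]:
    out: list[TEMatch] = []
    for cid, seq in candidates:
        qlen = len(seq)
        if qlen == 0:
            continue
        best_key: tuple | None = None
        best_match: TEMatch | None = None
        for name, target in library.items():
            for strand, q in (("+", seq.upper()), ("-", reverse_complement(seq).upper())):
                res = edlib.align(q, target, mode="HW", task="distance")
                dist = res["editDistance"]
                if dist < 0:
                    continue
                identity = 1.0 - dist / qlen
                if identity < min_identity:
                    continue
                key = (identity, qlen, name)
                match = TEMatch(
                    read_id=cid,
                    te_name=name,
                    aligned_len=qlen,
                    strand=strand,
                    query_len=qlen,
                )
                if best_key is None or _better(key, best_key):
                    best_key, best_match = key, match
        if best_match is not None:
            out.append(best_match)
    return out


def align_to_te_library(
    candidates: Sequence[tuple[str, str]],
    te_fasta: str,
    engine: str = "auto",
    preset: str = "map-pb",
    minimap2_path: str = "minimap2",
) -> list[TEMatch]:
    """Best TE-library hit per candidate sequence.

    ``candidates`` is a sequence of (id, sequence) pairs.  Candidates
    without a reportable alignment yield no :class:`TEMatch`.  Ties are
    broken by longer aligned length, then lexicographic target name.

    ``engine`` is ``minimap2``, ``edlib`` or ``auto`` (minimap2 when the
    binary is on PATH, else edlib).
    """
    library = load_te_library(te_fasta)  # validates the FASTA for both engines
    if engine == "auto":
        engine = "minimap2" if shutil.which(minimap2_path) else "edlib"
    if not candidates:
        return []
    if engine == "minimap2":
        return _align_minimap2(candidates, te_fasta, preset, minimap2_path)
    if engine == "edlib":
        return _align_edlib(candidates, library)
    raise ValueError(f"unknown alignment engine {engine!r}")


def filter_and_assign(
    cluster: CandidateCluster,
    matches: Sequence[TEMatch],
    params: Parameters,
    family_map: Mapping[str, str] | None = None,
) -> Optional[tuple[str, list[str]]]:
    """Apply the read-support and match-length filters to one cluster.

    A match is valid iff ``aligned_len >= match_fraction * query_len``.
    The cluster passes iff at least ``min_supporting_reads`` valid
    matches agree on one family (TE names mapped through ``family_map``
    when given).  Returns ``(family, supporting candidate ids)`` for the
    winning family, or ``None``.  Ties between families are broken by
    cumulative aligned length, then lexicographic family name.
    """
    per_family: dict[str, list[TEMatch]] = {}
    for m in matches:
        if m.aligned_len < params.match_fraction * m.query_len:
            continue
        family = family_map.get(m.te_name, m.te_name) if family_map else m.te_name
        per_family.setdefault(family, []).append(m)

    best: tuple[tuple, str] | None = None
    for family, fam_matches in per_family.items():
        key = (len(fam_matches), sum(m.aligned_len for m in fam_matches), family)
        if best is None or _better(key, best[0]):
            best = (key, family)
    if best is None:
        return None
    (count, _total, _), family = best[0], best[1]
    if count < params.min_supporting_reads:
        return None
    supporting = sorted(m.read_id for m in per_family[family])
    return family, supporting
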