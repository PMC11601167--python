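"""Benchmark scoring: per-family sensitivity and precision.

A call is a true positive when a truth insertion of the same family lies
within a positional window (default 50 bp) on the same contig; matching
is one-to-one and greedy by distance, so two calls cannot both claim a
single truth record.  Sensitivity = TP / truth count, precision =
TP / (TP + FP); a 0/0 ratio is reported as ``None``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .simulate import TruthRecord
from .vcfout import read_vcf_calls


@dataclass(frozen=True)
class SimpleCall:
    contig: str
    position: int
    family: str


def calls_from_vcf(path: str) -> list[SimpleCall]:
    return [
        SimpleCall(rec["contig"], rec["position"], rec["family"])
        for rec in read_vcf_calls(path)
    ]


def _match_family(
    calls: Sequence[SimpleCall], truths: Sequence[TruthRecord], window: int
) -> int:
    """Greedy one-to-one matching by distance; returns TP count."""
    pairs: list[tuple[int, int, int]] = []
    for ci, call in enumerate(calls):
        for ti, truth in enumerate(truths):
            if call.contig != truth.contig:
                continue
            dist = abs(call.position - truth.position)
            if dist <= window:
                pairs.append((dist, ci, ti))
    pairs.sort()
    used_calls: set[int] = set()
    used_truths: set[int] = set()
    tp = 0
    for _dist, ci, ti in pairs:
        if ci in used_calls or ti in used_truths:
            continue
        used_calls.add(ci)
        used_truths.add(ti)
        tp += 1
    return tp


def evaluate_calls(
    calls: Iterable[SimpleCall],
    truths: Iterable[TruthRecord],
    window: int = 50,
) -> dict[str, dict]:
    """Per-family TP/FN/FP, sensitivity and precision.

    Families present only in the calls report precision (0.0) but a
    ``None`` sensitivity; an empty call set reports ``None`` precision.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    calls = list(calls)
    truths = list(truths)
    families = sorted(
        {c.family for c in calls if c.family} | {t.family for t in truths}
    )
    out: dict[str, dict] = {}
    for family in families:
        fam_calls = [c for c in calls if c.family == family]
        fam_truths = [t for t in truths if t.family == family]
        tp = _match_family(fam_calls, fam_truths, window)
        fp = len(fam_calls) - tp
        fn = len(fam_truths) - tp
        out[family] = {
            "tp": tp,
            "fp": fp,
            "fn": fn,
            "n_truth": len(fam_truths),
            "n_calls": len(fam_calls),
            "sensitivity": tp / len(fam_truths) if fam_truths else None,
            "precision": tp / (tp + fp) if (tp + fp) > 0 else None,
        }
    return out
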