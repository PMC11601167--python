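"""Tunable parameters of the insertion caller.

All thresholds that govern evidence collection, clustering, TE
classification and evaluation live in one dataclass so that the CLI, the
library API and the test-suite share a single source of defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class Parameters:
    """Caller thresholds.

    Attributes
    ----------
    min_supporting_reads:
        Minimum number of candidate sequences that must match the same TE
        family for a cluster to become a call (default 3).
    cluster_eps:
        DBSCAN neighbourhood radius in bp for breakpoint clustering.
    cluster_min_points:
        Minimum neighbourhood size for a DBSCAN core point. ``None`` ties
        it to ``min_supporting_reads`` (one knob controls both, mirroring
        the single read-support option of the CLI).
    min_insertion_len:
        Shortest CIGAR insertion operation kept as evidence, bp.
    min_clip_len:
        Shortest soft-clipped segment kept as evidence, bp.
    min_mapq:
        Reads below this mapping quality are ignored.
    match_fraction:
        A TE-library match is valid only if its aligned length covers at
        least this fraction of the candidate sequence (default 0.10).
    match_window_bp:
        Positional window used when benchmarking calls against a truth
        set (evaluation only, not used by the caller itself).
    haplotype_purity:
        Fraction of haplotype-tagged supporting reads that must share one
        haplotype for a phased heterozygous call.
    hom_allele_fraction:
        Supporting/depth ratio above which an unphased call is upgraded
        to homozygous.
    """

    min_supporting_reads: int = 3
    cluster_eps: int = 100
    cluster_min_points: int | None = None
    min_insertion_len: int = 100
    min_clip_len: int = 150
    min_mapq: int = 10
    match_fraction: float = 0.10
    match_window_bp: int = 50
    haplotype_purity: float = 0.8
    hom_allele_fraction: float = 0.8

    def __post_init__(self) -> None:
        if self.min_supporting_reads < 1:
            raise ValueError("min_supporting_reads must be >= 1")
        if not (0 < self.match_fraction <= 1):
            raise ValueError("match_fraction must be in (0, 1]")
        if self.cluster_eps <= 0:
            raise ValueError("cluster_eps must be > 0")
        if self.cluster_min_points is not None and self.cluster_min_points < 1:
            raise ValueError("cluster_min_points must be >= 1")

    @property
    def effective_min_points(self) -> int:
        if self.cluster_min_points is None:
            return self.min_supporting_reads
        return self.cluster_min_points
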