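"""Density-based clustering of breakpoint positions.

Per-read breakpoints from the same insertion are scattered over a few bp
by alignment jitter; DBSCAN on the 1-D position axis groups them into
candidate loci while isolated stray breakpoints fall out as noise.  The
implementation below is the textbook DBSCAN algorithm specialised to
sorted integer positions: the epsilon-neighbourhood is a binary-searched
window, which keeps the scan O(n log n) while remaining label-equivalent
to the generic algorithm (points processed in ascending position order).
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .evidence import InsertionEvidence
from .params import Parameters

NOISE = -1


@dataclass
class CandidateCluster:
    """A DBSCAN cluster of insertion evidence on one contig."""

    contig: str
    members: list[InsertionEvidence]
    id: int = 0

    @property
    def positions(self) -> list[int]:
        return [m.position for m in self.members]

    @property
    def position_min(self) -> int:
        return min(self.positions)

    @property
    def position_max(self) -> int:
        return max(self.positions)

    def __len__(self) -> int:
        return len(self.members)


def dbscan_1d(positions: Sequence[int], eps: int, min_points: int) -> list[int]:
    """Cluster sorted 1-D positions with DBSCAN.

    Returns one label per position; noise points get ``-1``.  Cluster
    labels are renumbered so cluster 0 contains the leftmost clustered
    point.  ``positions`` must be sorted ascending.

    A point is a core point when at least ``min_points`` positions
    (itself included) lie within ``eps``; clusters are the maximal
    density-connected sets, and border points join the first cluster that
    reaches them in left-to-right processing order.
    """
    if eps <= 0:
        raise ValueError("eps must be > 0")
    if min_points < 1:
        raise ValueError("min_points must be >= 1")
    n = len(positions)
    if n == 0:
        return []
    if any(positions[i] > positions[i + 1] for i in range(n - 1)):
        raise ValueError("positions must be sorted ascending")

    def neighbourhood(i: int) -> range:
        p = positions[i]
        lo = bisect_left(positions, p - eps)
        hi = bisect_right(positions, p + eps)
        return range(lo, hi)

    labels = [NOISE] * n
    visited = [False] * n
    cluster = 0
    for i in range(n):
        if visited[i]:
            continue
        visited[i] = True
        nbrs = neighbourhood(i)
        if len(nbrs) < min_points:
            continue  # noise unless later claimed as a border point
        labels[i] = cluster
        queue = deque(nbrs)
        while queue:
            j = queue.popleft()
            if labels[j] == NOISE:
                labels[j] = cluster  # border point
            if visited[j]:
                continue
            visited[j] = True
            labels[j] = cluster
            j_nbrs = neighbourhood(j)
            if len(j_nbrs) >= min_points:
                queue.extend(j_nbrs)
        cluster += 1

    # renumber by leftmost member for determinism
    remap: dict[int, int] = {}
    for lab in labels:
        if lab != NOISE and lab not in remap:
            remap[lab] = len(remap)
    return [remap[lab] if lab != NOISE else NOISE for lab in labels]


def build_clusters(
    evidence: Iterable[InsertionEvidence], params: Parameters
) -> list[CandidateCluster]:
    """Group evidence per contig and DBSCAN-cluster the positions.

    Noise evidence is discarded.  Clusters are sorted by
    (contig, position_min) and numbered sequentially.
    """
    by_contig: dict[str, list[InsertionEvidence]] = {}
    for ev in evidence:
        by_contig.setdefault(ev.contig, []).append(ev)

    clusters: list[CandidateCluster] = []
    for contig in sorted(by_contig):
        members = sorted(
            by_contig[contig], key=lambda ev: (ev.position, ev.read_id, ev.kind.value)
        )
        labels = dbscan_1d(
            [m.position for m in members],
            eps=params.cluster_eps,
            min_points=params.effective_min_points,
        )
        grouped: dict[int, list[InsertionEvidence]] = {}
        for member, lab in zip(members, labels):
            if lab != NOISE:
                grouped.setdefault(lab, []).append(member)
        for lab in sorted(grouped):
            clusters.append(CandidateCluster(contig=contig, members=grouped[lab]))

    clusters.sort(key=lambda c: (c.contig, c.position_min))
    for i, c in enumerate(clusters):
        c.id = i
    return clusters


def clusters_to_bed(clusters: Iterable[CandidateCluster]) -> str:
    """Debug dump: one BED line per cluster (contig, min, max+1, n_members)."""
    lines = [
        f"{c.contig}\t{c.position_min}\t{c.position_max + 1}\tcluster_{c.id}\t{len(c)}"
        for c in clusters
    ]
    return "\n".join(lines) + ("\n" if lines else "")
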