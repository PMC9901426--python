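"""Tail-module detection by 1-D density-based clustering.

Predicted tail proteins are points on the gene-index axis; distance is
the difference of protein ordinals (protein spacing, not nucleotide
distance, so protein-length variation cannot bias the clustering).
Standard DBSCAN semantics apply: a point is core iff at least ``minpts``
points (itself included) lie within ``eps``; clusters are maximal
density-connected sets; border points attach to the cluster whose core
point reaches them first in left-to-right scan order, which makes the
otherwise order-dependent border assignment deterministic.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

#: Cluster label for points assigned to no cluster.
OUTLIER = "outlier"


@dataclass(frozen=True)
class ClusterParams:
    """eps in protein-index units; minpts counts the point itself."""

    eps: float = 6.0
    minpts: int = 4

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise ValueError(f"eps must be > 0, got {self.eps}")
        if self.minpts < 1:
            raise ValueError(f"minpts must be >= 1, got {self.minpts}")


@dataclass(frozen=True)
class TailCluster:
    cluster_id: int
    member_ordinals: tuple[int, ...]
    core_ordinals: tuple[int, ...]

    @property
    def span(self) -> tuple[int, int]:
        return (self.member_ordinals[0], self.member_ordinals[-1])

    @property
    def n_members(self) -> int:
        return len(self.member_ordinals)


def dbscan_1d(
    points: Sequence[int], params: ClusterParams = ClusterParams()
) -> tuple[list[TailCluster], list[int]]:
    """Cluster 1-D integer points with DBSCAN.

    Returns (clusters ordered by leftmost member and numbered 0,1,...,
    sorted outlier list).  Duplicate points raise; an empty input yields
    no clusters and no outliers.
    """
    pts = sorted(points)
    if len(set(pts)) != len(pts):
        raise ValueError("duplicate ordinals in point set")
    if not pts:
        return [], []

    n = len(pts)
    # neighborhood sizes via two-pointer sweep over the sorted axis
    nbr: list[range] = []
    lo = hi = 0
    for i, p in enumerate(pts):
        while pts[lo] < p - params.eps:
            lo += 1
        hi = max(hi, i)
        while hi + 1 < n and pts[hi + 1] <= p + params.eps:
            hi += 1
        nbr.append(range(lo, hi + 1))
    is_core = [len(nbr[i]) >= params.minpts for i in range(n)]

    label = [-1] * n  # -1 = unassigned/outlier
    next_id = 0
    for i in range(n):  # left-to-right scan fixes border ties
        if label[i] != -1 or not is_core[i]:
            continue
        cid = next_id
        next_id += 1
        label[i] = cid
        queue = deque([i])
        while queue:
            j = queue.popleft()
            if not is_core[j]:
                continue
            for k in nbr[j]:
                if label[k] == -1:
                    label[k] = cid
                    queue.append(k)

    clusters = []
    for cid in range(next_id):
        members = tuple(pts[i] for i in range(n) if label[i] == cid)
        cores = tuple(pts[i] for i in range(n) if label[i] == cid and is_core[i])
        clusters.append(TailCluster(cid, members, cores))
    clusters.sort(key=lambda c: c.member_ordinals[0])
    clusters = [
        TailCluster(i, c.member_ordinals, c.core_ordinals)
        for i, c in enumerate(clusters)
    ]
    outliers = [pts[i] for i in range(n) if label[i] == -1]
    return clusters, outliers


def census(
    cluster_counts: Mapping[str, int], morphology: Mapping[str, str] | None = None
) -> list[dict]:
    """Tabulate genomes by morphology and number of tail modules.

    ``cluster_counts`` maps genome_id -> number of clusters found (0 when
    the tail calls were too sparse to form any).  Categories are mutually
    exclusive: 0, 1, 2, 3 and 4+ clusters; percentages are relative to
    the morphology's genome count.
    """
    morphology = morphology or {}
    by_morph: dict[str, list[int]] = {}
    for gid, count in cluster_counts.items():
        m = morphology.get(gid, "unknown")
        by_morph.setdefault(m, []).append(count)

    rows = []
    for m in sorted(by_morph):
        counts = by_morph[m]
        total = len(counts)
        for cat, pred in (
            ("0", lambda c: c == 0),
            ("1", lambda c: c == 1),
            ("2", lambda c: c == 2),
            ("3", lambda c: c == 3),
            ("4+", lambda c: c >= 4),
        ):
            k = sum(1 for c in counts if pred(c))
            rows.append(
                {
                    "morphology": m,
                    "clusters": cat,
                    "n_genomes": k,
                    "percent": 100.0 * k / total,
                }
            )
    return rows


def tune_params(
    genomes: Mapping[str, Sequence[int]],
    truth_single_cluster: Mapping[str, bool] | None = None,
    eps_grid: Iterable[float] = range(1, 11),
    minpts_grid: Iterable[int] = range(2, 9),
) -> tuple[ClusterParams, float]:
    """Grid-search eps/minpts scoring agreement with single-module truth.

    For each parameter pair, score the fraction of genomes whose tail
    calls collapse into exactly one cluster (or, when
    ``truth_single_cluster`` is given, whose single-cluster status matches
    it).  Returns the best parameters and their score; ties prefer
    smaller eps then smaller minpts.
    """
    best: tuple[float, float, int] | None = None
    for eps in eps_grid:
        for minpts in minpts_grid:
            params = ClusterParams(eps=float(eps), minpts=int(minpts))
            hits = 0
            for gid, pts in genomes.items():
                clusters, _ = dbscan_1d(pts, params)
                single = len(clusters) == 1
                want = True if truth_single_cluster is None else truth_single_cluster.get(gid, True)
                hits += single == want
            score = hits / len(genomes) if genomes else 0.0
            key = (-score, float(eps), int(minpts))
            if best is None or key < (best[0], best[1], best[2]):
                best = key
    assert best is not None
    return ClusterParams(eps=best[1], minpts=best[2]), -best[0]


def write_clusters(
    per_genome: Mapping[str, tuple[list[TailCluster], list[int]]],
    path: str | Path,
    protein_ids: Mapping[str, Mapping[int, str]] | None = None,
) -> None:
    """Write cluster TSV: genome_id, cluster_id, start/end ordinal,
    n_members, comma-joined member protein ids (ordinals if unknown)."""
    protein_ids = protein_ids or {}
    with open(path, "w") as fh:
        fh.write("genome_id\tcluster_id\tstart_ordinal\tend_ordinal\tn_members\tmembers\n")
        for gid in sorted(per_genome):
            clusters, _ = per_genome[gid]
            names = protein_ids.get(gid, {})
            for c in clusters:
                members = ",".join(str(names.get(o, o)) for o in c.member_ordinals)
                fh.write(
                    f"{gid}\t{c.cluster_id}\t{c.span[0]}\t{c.span[1]}\t{c.n_members}\t{members}\n"
                )
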