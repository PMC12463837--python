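"""Sampling prioritization: diversity panels and bridge-population scores.

Two ways to pick representative varieties for genomic sampling from a
distance matrix. Farthest-point (maximin) greedy selection operationalizes
"maximize captured diversity with minimal redundancy": it starts from the
most distant pair and repeatedly adds the variety farthest from the panel,
carrying the classic 2-approximation guarantee on the maximin radius.
Cluster-medoid selection instead returns one representative per cluster of
a supplied partition.

Bridge populations — varieties lexically intermediate between two
clusters, signalling contact or admixture — are scored with a
silhouette-style ratio s = 1 - d_nearest / d_second over mean distances to
the two closest clusters (own cluster included): s near 0 means the
variety sits between clusters, s near 1 means it is well nested in its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import inf

import numpy as np

from .wordlist_io import DistanceMatrix, ValidationError

__all__ = [
    "Panel",
    "BridgeScore",
    "select_maximin",
    "select_medoids",
    "bridge_scores",
]

#: Default s threshold below which a variety is reported as a bridge.
BRIDGE_THRESHOLD = 0.15


@dataclass
class Panel:
    """An ordered selection of varieties.

    ``coverage[i]`` is the distance from the i-th selected variety to the
    nearest earlier selection at the moment it was added (infinite for the
    very first pick, which has no predecessor).
    """

    selected: list[str]
    coverage: list[float]
    method: str


@dataclass(order=True)
class BridgeScore:
    """Intermediacy of one variety between its two closest clusters.

    ``s = 1 - d_nearest / d_second`` with the two mean cluster distances
    ordered so d_nearest <= d_second; ``s`` is None for varieties whose
    own cluster is a singleton (own-cluster distance undefined).
    """

    s: float | None = field(compare=False)
    variety: str = field(compare=False)
    nearest: str | int = field(compare=False)
    second: str | int = field(compare=False)
    d_nearest: float = field(compare=False)
    d_second: float = field(compare=False)
    singleton: bool = field(compare=False, default=False)


def select_maximin(
    d: DistanceMatrix,
    k: int,
    seed_policy: str = "max-pair",
    start: str | None = None,
) -> Panel:
    """Farthest-point greedy panel of size k.

    ``seed_policy='max-pair'`` starts with the pair attaining the matrix
    maximum (lexicographically smallest such pair); ``'given-start'``
    starts from ``start``. Subsequent picks maximize the minimum distance
    to the current panel; ties break lexicographically.
    """
    n = len(d)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range [1, {n}]")
    labels = d.labels
    order = np.argsort(np.array(labels, dtype=object))  # lexicographic tie-break
    values = d.values

    selected: list[int] = []
    coverage: list[float] = []
    if seed_policy == "max-pair":
        best = (-inf, None)
        for a_pos in range(n):
            for b_pos in range(n):
                a, b = order[a_pos], order[b_pos]
                if a == b:
                    continue
                if values[a, b] > best[0]:
                    best = (values[a, b], (a, b))
        a, b = best[1]
        selected.append(int(a))
        coverage.append(inf)
        if k > 1:
            selected.append(int(b))
            coverage.append(float(best[0]))
    elif seed_policy == "given-start":
        if start is None:
            raise ValueError("seed_policy='given-start' requires start")
        selected.append(d.index(start))
        coverage.append(inf)
    else:
        raise ValueError(f"unknown seed_policy {seed_policy!r}")

    while len(selected) < k:
        mindist = values[:, selected].min(axis=1)
        best_val, best_idx = -inf, None
        for pos in order:
            if pos in selected:
                continue
            if mindist[pos] > best_val:
                best_val, best_idx = mindist[pos], int(pos)
        selected.append(best_idx)
        coverage.append(float(best_val))
    return Panel(
        selected=[labels[i] for i in selected],
        coverage=coverage,
        method="maximin",
    )


def select_medoids(d: DistanceMatrix, partition: dict[str, object]) -> Panel:
    """One medoid per cluster: the member minimizing the sum of distances
    to its cluster co-members (ties break lexicographically). Clusters are
    reported in sorted cluster-label order."""
    _check_partition(d, partition)
    clusters = _group(partition)
    selected: list[str] = []
    coverage: list[float] = []
    for cluster in sorted(clusters, key=str):
        members = sorted(clusters[cluster])
        idx = [d.index(m) for m in members]
        sums = d.values[np.ix_(idx, idx)].sum(axis=1)
        best = members[int(np.argmin(sums))]  # argmin takes the first = lexicographic
        selected.append(best)
        coverage.append(float(sums.min()))
    return Panel(selected=selected, coverage=coverage, method="medoid")


def bridge_scores(d: DistanceMatrix, partition: dict[str, object]) -> list[BridgeScore]:
    """Intermediacy score for every variety, sorted descending by s
    (singletons, whose s is undefined, come last)."""
    _check_partition(d, partition)
    clusters = _group(partition)
    if len(clusters) < 2:
        raise ValidationError("bridge scores need at least 2 clusters")
    out: list[BridgeScore] = []
    for v in d.labels:
        own = partition[v]
        own_others = [m for m in clusters[own] if m != v]
        mean_to = lambda members: float(
            np.mean([d.values[d.index(v), d.index(m)] for m in members])
        )
        foreign = {c: mean_to(ms) for c, ms in clusters.items() if c != own}
        near_foreign = min(sorted(foreign, key=str), key=lambda c: foreign[c])
        if not own_others:
            out.append(
                BridgeScore(
                    s=None,
                    variety=v,
                    nearest=own,
                    second=near_foreign,
                    d_nearest=0.0,
                    d_second=foreign[near_foreign],
                    singleton=True,
                )
            )
            continue
        d_own = mean_to(own_others)
        d_for = foreign[near_foreign]
        if d_own <= d_for:
            d_near, d_sec, c_near, c_sec = d_own, d_for, own, near_foreign
        else:
            d_near, d_sec, c_near, c_sec = d_for, d_own, near_foreign, own
        s = 0.0 if d_sec == 0 else 1.0 - d_near / d_sec
        out.append(
            BridgeScore(
                s=s,
                variety=v,
                nearest=c_near,
                second=c_sec,
                d_nearest=d_near,
                d_second=d_sec,
            )
        )
    scored = [b for b in out if b.s is not None]
    singles = [b for b in out if b.s is None]
    scored.sort(key=lambda b: (-b.s, b.variety))
    return scored + sorted(singles, key=lambda b: b.variety)


def _check_partition(d: DistanceMatrix, partition: dict[str, object]) -> None:
    missing = [x for x in d.labels if x not in partition]
    if missing:
        raise ValidationError(f"partition does not cover labels: {missing}")


def _group(partition: dict[str, object]) -> dict[object, list[str]]:
    clusters: dict[object, list[str]] = {}
    for label, cluster in partition.items():
        clusters.setdefault(cluster, []).append(label)
    if any(not ms for ms in clusters.values()):
        raise ValidationError("empty cluster")
    return clusters
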