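"""Complete-linkage clustering of binding sites with a free-energy cutoff.

Sites are clustered on the distance d = 1 - CS.  The dendrogram is cut at
the height whose induced partition minimizes

    F(partition) = - sum_C (|C|/N) * mean pairwise similarity within C
                   + T * sum_C (|C|/N) * (-ln(|C|/N))

i.e. an energy term rewarding tight clusters and a temperature-weighted
description-complexity (entropy) term penalizing fragmented partitions.
Singletons contribute zero energy.  Lower F is better; ties prefer the
smaller cutoff (more clusters).

The similarity fed to F is the *bit-score* matrix, not CS: bit scores are
negative for genuinely dissimilar sites, so a cluster of unrelated sites
costs energy and the all-singleton partition can win — with a similarity
bounded below by zero, one all-inclusive cluster (zero entropy, energy
<= 0) would always beat it.  The size weight |C|/N makes the energy of a
homogeneous cluster independent of how the dendrogram subdivides it, so
splitting a tight cluster is never rewarded.  The functional form lives in
a single function (:func:`free_energy`) so an alternative formulation is a
one-function swap.

The agglomeration itself is a deterministic O(n^3) complete-linkage pass:
clusters carry creation indices (leaves 0..n-1, merged clusters n, n+1, ...)
and ties in the merge distance are broken by the lowest (i, j) index pair.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class Merge:
    height: float
    left: int              # creation index of one merged cluster
    right: int
    index: int             # creation index of the new cluster
    members: tuple[int, ...]


@dataclass
class Dendrogram:
    n_leaves: int
    merges: list[Merge]

    def heights(self) -> list[float]:
        return [m.height for m in self.merges]

    def partition_at(self, cutoff: float) -> list[list[int]]:
        """Partition induced by applying all merges with height <= cutoff."""
        parent = list(range(self.n_leaves))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for m in self.merges:
            if m.height <= cutoff:
                roots = {find(i) for i in m.members}
                target = min(roots)
                for r in roots:
                    parent[r] = target
        groups: dict[int, list[int]] = {}
        for i in range(self.n_leaves):
            groups.setdefault(find(i), []).append(i)
        return [sorted(g) for g in sorted(groups.values())]

    def to_newick(self) -> str:
        """Nested-text rendering of the merge history for inspection."""
        labels = {i: str(i) for i in range(self.n_leaves)}
        for m in self.merges:
            labels[m.index] = f"({labels[m.left]},{labels[m.right]}):{m.height:.6g}"
        if not self.merges:
            return ",".join(labels[i] for i in range(self.n_leaves)) + ";"
        return labels[self.merges[-1].index] + ";"


@dataclass
class ClusteringResult:
    clusters: list[list[int]]
    cutoff: float
    dendrogram: Dendrogram
    free_energy_trace: list[tuple[float, float]]

    def to_json(self) -> str:
        return json.dumps({
            "clusters": self.clusters,
            "cutoff": self.cutoff,
            "free_energy_trace": [[c, f] for c, f in self.free_energy_trace],
            "dendrogram": self.dendrogram.to_newick(),
        }, indent=2)


def distance_from_similarity(similarity: np.ndarray) -> np.ndarray:
    """d(i,j) = 1 - CS(i,j); diagonal forced to 0."""
    sim = np.asarray(similarity, dtype=float)
    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    return dist


def _validate_distance(dist: np.ndarray) -> np.ndarray:
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(dist, dist.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(dist) != 0):
        raise ValueError("distance matrix must have zero diagonal")
    return dist


def complete_linkage(dist: np.ndarray) -> Dendrogram:
    """Agglomerative complete-linkage merge history.

    Cluster-pair distance = max over member pairs.  At each step the pair at
    minimal distance merges; exact ties break on the lowest pair of cluster
    creation indices.
    """
    dist = _validate_distance(dist)
    n = dist.shape[0]
    active: dict[int, tuple[int, ...]] = {i: (i,) for i in range(n)}
    merges: list[Merge] = []
    next_index = n
    while len(active) > 1:
        best = None
        ids = sorted(active)
        for ai, i in enumerate(ids):
            for j in ids[ai + 1:]:
                d = max(dist[a, b] for a in active[i] for b in active[j])
                if best is None or d < best[0] or (d == best[0] and (i, j) < best[1:]):
                    best = (d, i, j)
        d, i, j = best
        members = tuple(sorted(active[i] + active[j]))
        merges.append(Merge(float(d), i, j, next_index, members))
        del active[i], active[j]
        active[next_index] = members
        next_index += 1
    return Dendrogram(n, merges)


def free_energy(partition: list[list[int]], similarity: np.ndarray,
                temperature: float, n_total: int | None = None) -> float:
    """F = -sum_C (|C|/N) * (mean within-cluster similarity) + T * entropy.

    The entropy term is sum over clusters of (|C|/N) ln(N/|C|); singletons
    contribute zero to the energy term, so the all-singleton partition has
    F = T ln N exactly.  Lower is better.
    """
    if not partition:
        raise ValueError("partition must be non-empty")
    if temperature <= 0 or not math.isfinite(temperature):
        raise ValueError("temperature must be finite and positive")
    sim = np.asarray(similarity, dtype=float)
    n = n_total if n_total is not None else sum(len(c) for c in partition)
    if sum(len(c) for c in partition) != n:
        raise ValueError("partition does not cover all sites")
    energy = 0.0
    entropy = 0.0
    for cluster in partition:
        k = len(cluster)
        if k >= 2:
            pair_sum = sum(sim[a, b] for ai, a in enumerate(cluster)
                           for b in cluster[ai + 1:])
            energy -= (k / n) * pair_sum / (k * (k - 1) / 2)
        p = k / n
        entropy += p * (-math.log(p)) if p < 1.0 else 0.0
    return energy + temperature * entropy


def select_cutoff(dendrogram: Dendrogram, similarity: np.ndarray,
                  temperature: float) -> ClusteringResult:
    """Evaluate F at every distinct merge height (plus 0 and 1) and return
    the minimal-F partition; ties take the smaller cutoff."""
    candidates = sorted({0.0, 1.0} | set(dendrogram.heights()))
    trace = []
    best = None
    for cutoff in candidates:
        partition = dendrogram.partition_at(cutoff)
        f = free_energy(partition, similarity, temperature)
        trace.append((cutoff, f))
        if best is None or f < best[0] - 1e-12:
            best = (f, cutoff, partition)
    _, cutoff, partition = best
    return ClusteringResult(partition, cutoff, dendrogram, trace)
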