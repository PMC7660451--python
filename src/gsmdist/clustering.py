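"""Per-metric hierarchical clustering and cluster-ensemble consensus.

Each distance matrix is clustered with average-linkage (UPGMA) agglomerative
clustering cut to exactly k clusters. The three metric-wise label vectors are
then reconciled by three classic cluster-ensemble algorithms:

* **CSPA** — cluster-based similarity partitioning: the co-association matrix
  (fraction of labelings placing two models together) is treated as a
  similarity and re-clustered.
* **HGPA** — hypergraph partitioning: every cluster of every labeling is a
  hyperedge; a balanced k-way partition minimizing the number of cut
  hyperedges is sought by a seeded greedy local search with restarts.
* **MCLA** — meta-clustering: the input clusters themselves are clustered (by
  Jaccard distance between their indicator vectors) into k meta-clusters and
  each model joins the meta-cluster it participates in most.

The definitive consensus is the candidate with the highest mean normalized
mutual information (NMI, arithmetic-mean normalization) against the input
labelings; ties break lexicographically by algorithm name.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import squareform

from .metrics import DistanceMatrix
from .model import ValidationError

__all__ = [
    "Labeling",
    "ConsensusResult",
    "hierarchical_labels",
    "nmi",
    "cspa",
    "hgpa",
    "mcla",
    "consensus",
]


@dataclass(frozen=True)
class Labeling:
    """Assignment of every model to a cluster index in 0..k−1 (dense)."""

    labels: dict[str, int]

    def __post_init__(self) -> None:
        if not self.labels:
            raise ValidationError("labeling must cover at least one model")
        used = sorted(set(self.labels.values()))
        if used != list(range(len(used))):
            raise ValidationError(f"cluster indices not dense in 0..k-1: {used}")

    @property
    def k(self) -> int:
        return max(self.labels.values()) + 1

    @property
    def ids(self) -> list[str]:
        return sorted(self.labels)

    def array(self, order: Sequence[str] | None = None) -> np.ndarray:
        order = list(order) if order is not None else self.ids
        return np.array([self.labels[i] for i in order], dtype=int)

    @classmethod
    def from_array(cls, ids: Sequence[str], arr: Sequence[int]) -> "Labeling":
        return cls(dict(zip(ids, (int(x) for x in _densify(np.asarray(arr, int))))))


def _densify(arr: np.ndarray) -> np.ndarray:
    """Relabel cluster indices densely by first occurrence (order-stable)."""
    mapping: dict[int, int] = {}
    out = np.empty_like(arr)
    for i, v in enumerate(arr):
        if v not in mapping:
            mapping[v] = len(mapping)
        out[i] = mapping[v]
    return out


def hierarchical_labels(d: DistanceMatrix, k: int) -> Labeling:
    """Average-linkage (UPGMA) agglomerative clustering cut to exactly k clusters."""
    n = d.n
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, {n}], got {k}")
    Z = linkage(squareform(d.values, checks=False), method="average")
    labels = cut_tree(Z, n_clusters=k).ravel()
    return Labeling.from_array(d.ids, labels)


def nmi(a: Labeling, b: Labeling) -> float:
    """Normalized mutual information, arithmetic-mean normalization, ∈ [0, 1].

    Invariant to relabeling of cluster indices; 0 by convention when either
    labeling has a single cluster (zero entropy).
    """
    if set(a.labels) != set(b.labels):
        raise ValidationError("labelings cover different model sets")
    from sklearn.metrics import normalized_mutual_info_score

    order = a.ids
    return float(
        normalized_mutual_info_score(
            a.array(order), b.array(order), average_method="arithmetic"
        )
    )


def _common_ids(labelings: Sequence[Labeling]) -> list[str]:
    if not labelings:
        raise ValueError("need at least one labeling")
    ids = set(labelings[0].labels)
    for lab in labelings[1:]:
        if set(lab.labels) != ids:
            raise ValidationError("labelings cover different model sets")
    return sorted(ids)


def _coassociation(labelings: Sequence[Labeling], ids: Sequence[str]) -> np.ndarray:
    arrays = [lab.array(ids) for lab in labelings]
    n = len(ids)
    C = np.zeros((n, n))
    for arr in arrays:
        C += (arr[:, None] == arr[None, :]).astype(float)
    return C / len(arrays)


def cspa(labelings: Sequence[Labeling], k: int) -> Labeling:
    """Cluster-based similarity partitioning: re-cluster the co-association matrix."""
    ids = _common_ids(labelings)
    C = _coassociation(labelings, ids)
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    return hierarchical_labels(DistanceMatrix(list(ids), D, "coassociation"), k)


def _hyperedges(labelings: Sequence[Labeling], ids: Sequence[str]) -> list[np.ndarray]:
    edges = []
    for lab in labelings:
        arr = lab.array(ids)
        for c in range(lab.k):
            members = np.where(arr == c)[0]
            if members.size:
                edges.append(members)
    return edges


def _cut_value(assignment: np.ndarray, edges: Sequence[np.ndarray]) -> int:
    return sum(1 for e in edges if len(set(assignment[e])) > 1)


def hgpa(labelings: Sequence[Labeling], k: int, seed: int = 0, restarts: int = 20) -> Labeling:
    """Greedy balanced hyperedge-cut minimization with seeded random restarts.

    Every input cluster is a hyperedge; the returned k-way partition
    heuristically minimizes the number of hyperedges spanning more than one
    part, with part sizes constrained to ±25% of n/k.
    """
    ids = _common_ids(labelings)
    n = len(ids)
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, {n}], got {k}")
    edges = _hyperedges(labelings, ids)
    target = n / k
    size_min = max(1, int(np.floor(0.75 * target)))
    size_max = int(np.ceil(1.25 * target))
    rng = np.random.default_rng(seed)

    best: np.ndarray | None = None
    best_cut = np.inf
    for _ in range(restarts):
        perm = rng.permutation(n)
        assignment = np.empty(n, int)
        assignment[perm] = np.arange(n) % k  # balanced round-robin start
        sizes = np.bincount(assignment, minlength=k)
        cut = _cut_value(assignment, edges)
        improved = True
        while improved:
            improved = False
            for i in range(n):
                current = assignment[i]
                for c in range(k):
                    if c == current:
                        continue
                    if sizes[c] + 1 > size_max or sizes[current] - 1 < size_min:
                        continue
                    assignment[i] = c
                    new_cut = _cut_value(assignment, edges)
                    if new_cut < cut:
                        cut = new_cut
                        sizes[current] -= 1
                        sizes[c] += 1
                        current = c
                        improved = True
                    else:
                        assignment[i] = current
        if cut < best_cut:
            best_cut = cut
            best = assignment.copy()
    assert best is not None
    return Labeling.from_array(ids, best)


def mcla(labelings: Sequence[Labeling], k: int) -> Labeling:
    """Meta-clustering: cluster the input clusters, then assign by participation.

    Indicator vectors of all input clusters are grouped into k meta-clusters
    by average-linkage on Jaccard distance; each model joins the meta-cluster
    with maximal average participation (ties → lowest meta-cluster index).
    """
    ids = _common_ids(labelings)
    n = len(ids)
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, {n}], got {k}")
    edges = _hyperedges(labelings, ids)
    indicators = np.zeros((len(edges), n))
    for e_idx, members in enumerate(edges):
        indicators[e_idx, members] = 1.0
    m = len(edges)
    if m < k:
        raise ValueError(f"fewer input clusters ({m}) than requested meta-clusters ({k})")
    inter = indicators @ indicators.T
    sizes = indicators.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    J = 1.0 - np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    np.fill_diagonal(J, 0.0)
    J = (J + J.T) / 2.0
    Z = linkage(squareform(J, checks=False), method="average")
    meta = cut_tree(Z, n_clusters=k).ravel()
    # participation of each model in each meta-cluster
    participation = np.zeros((n, k))
    for c in range(k):
        members = meta == c
        participation[:, c] = indicators[members].mean(axis=0) if members.any() else 0.0
    assignment = participation.argmax(axis=1)  # argmax returns lowest index on ties
    return Labeling.from_array(ids, assignment)


@dataclass
class ConsensusResult:
    """Candidate consensus labelings, their mean-NMI scores, and the winner."""

    input_labelings: list[Labeling]
    candidates: dict[str, Labeling]
    scores: dict[str, float]
    selected: str

    @property
    def labeling(self) -> Labeling:
        return self.candidates[self.selected]


def consensus(labelings: Sequence[Labeling], k: int, seed: int = 0) -> ConsensusResult:
    """Run CSPA, HGPA and MCLA; keep the candidate with highest mean NMI.

    Ties break lexicographically by algorithm name (CSPA < HGPA < MCLA).
    """
    if len(labelings) < 2:
        raise ValueError("consensus needs at least 2 input labelings")
    candidates = {
        "CSPA": cspa(labelings, k),
        "HGPA": hgpa(labelings, k, seed=seed),
        "MCLA": mcla(labelings, k),
    }
    scores = {
        name: float(np.mean([nmi(cand, lab) for lab in labelings]))
        for name, cand in candidates.items()
    }
    selected = min(scores, key=lambda name: (-scores[name], name))
    return ConsensusResult(list(labelings), candidates, scores, selected)
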