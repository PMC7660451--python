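"""Pairwise distance metrics over model sets.

Two of the three workflow metrics live here:

* **Jaccard distance** ``1 − |A∩B| / |A∪B|`` between the reaction sets of two
  models, computed on binary presence vectors aligned to a template reaction
  universe. This is the de-facto standard similarity for genome-scale
  reconstructions.
* **Weisfeiler-Lehman subtree (WLS) kernel distance** between the bipartite
  metabolite-reaction graphs of two models. The WL kernel counts matching
  node labels over ``h`` rounds of iterative label refinement (each node is
  relabeled by its own label plus the sorted multiset of neighbor labels);
  the kernel is the integer dot product of the resulting count vectors.
  Distances are ``1 − k(x,y)/√(k(x,x)·k(y,y))`` (cosine normalization), so
  values are comparable across models of different sizes and live on [0, 1]
  like the Jaccard distance.

Highly connected cofactors ("currency metabolites": water, ATP, NADH, ...)
are removed from the graphs before kernel computation — they connect almost
everything to everything and would swamp the topology signal.

The third metric (flux-distribution correlation) is in
:mod:`gsmdist.sampling`.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import PresenceVector, ReactionUniverse, presence_vector
from .model import MetabolicModel, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "CurrencyPolicy",
    "DEFAULT_CURRENCY_IDS",
    "ModelGraph",
    "jaccard_distance",
    "jaccard_matrix",
    "build_model_graph",
    "wls_kernel",
    "wls_distance_matrix",
]


# ---------------------------------------------------------------------------
# distance matrix container
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    """Labeled symmetric pairwise distance matrix for one metric."""

    ids: list[str]
    values: np.ndarray
    metric_name: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValidationError(
                f"distance matrix shape {self.values.shape} does not match {n} ids"
            )
        if not np.isfinite(self.values).all():
            raise ValidationError("distance matrix contains non-finite values")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValidationError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0, atol=1e-12):
            raise ValidationError("distance matrix diagonal is not zero")
        if (self.values < -1e-12).any():
            raise ValidationError("distance matrix has negative entries")

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        frame = pd.DataFrame(self.values, index=self.ids, columns=self.ids)
        frame.to_csv(path, sep="\t", index_label="model_id", float_format="%.12g")
        return path

    @classmethod
    def from_tsv(cls, path: str | Path, metric_name: str = "") -> "DistanceMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(frame.index), frame.to_numpy(float), metric_name)

    def condensed(self) -> np.ndarray:
        """Strictly-upper-triangle entries, row-major (scipy condensed form)."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


# ---------------------------------------------------------------------------
# Jaccard
# ---------------------------------------------------------------------------


def jaccard_distance(a: PresenceVector, b: PresenceVector) -> float:
    """1 − |A∩B|/|A∪B| between the supported reaction sets of two vectors."""
    if a.universe.ids != b.universe.ids:
        raise ValidationError(
            f"presence vectors of {a.model_id!r} and {b.model_id!r} use different universes"
        )
    inter = int(np.sum((a.bits == 1) & (b.bits == 1)))
    union = int(np.sum((a.bits == 1) | (b.bits == 1)))
    if union == 0:
        logger.warning(
            "both %r and %r have empty reaction sets; Jaccard distance defined as 0",
            a.model_id,
            b.model_id,
        )
        return 0.0
    return 1.0 - inter / union


def jaccard_matrix(
    models: Sequence[MetabolicModel],
    universe: ReactionUniverse,
    strict: bool = True,
) -> DistanceMatrix:
    """Pairwise Jaccard distance between the reaction lists of every model pair."""
    if len(models) < 2:
        raise ValueError("need at least 2 models")
    bits = np.stack(
        [presence_vector(m, universe, strict=strict).bits for m in models]
    ).astype(np.int64)
    inter = bits @ bits.T
    support = bits.sum(axis=1)
    union = support[:, None] + support[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = 1.0 - np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    np.fill_diagonal(dist, 0.0)
    return DistanceMatrix([m.id for m in models], dist, "jaccard")


# ---------------------------------------------------------------------------
# model graphs and the WLS kernel
# ---------------------------------------------------------------------------

#: Compartment-agnostic base ids of common currency metabolites (cofactors and
#: small inorganics that participate in a large fraction of all reactions).
DEFAULT_CURRENCY_IDS: tuple[str, ...] = (
    "h2o", "h", "atp", "adp", "amp", "pi", "ppi",
    "nad", "nadh", "nadp", "nadph", "fad", "fadh2",
    "co2", "o2", "coa",
)

_COMPARTMENT_SUFFIX = re.compile(r"(\[[a-zA-Z0-9]+\]|_[a-zA-Z0-9]+)$")


def strip_compartment(met_id: str) -> str:
    """Compartment-agnostic base id: drops a trailing ``_c``-style or ``[c]``-style tag."""
    return _COMPARTMENT_SUFFIX.sub("", met_id)


@dataclass(frozen=True)
class CurrencyPolicy:
    """Which metabolites to delete from graphs before kernel computation.

    Metabolites whose compartment-stripped base id is in ``ids`` are removed;
    if ``degree_threshold`` is set, metabolites participating in more than
    that many reactions are removed as well.
    """

    ids: tuple[str, ...] = DEFAULT_CURRENCY_IDS
    degree_threshold: int | None = None

    @classmethod
    def none(cls) -> "CurrencyPolicy":
        return cls(ids=(), degree_threshold=None)


@dataclass
class ModelGraph:
    """Undirected bipartite metabolite-reaction graph with categorical labels."""

    labels: dict[str, str]  # node id -> label
    adjacency: dict[str, list[str]]  # node id -> sorted neighbor ids

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def n_edges(self) -> int:
        return sum(len(v) for v in self.adjacency.values()) // 2


def build_model_graph(
    model: MetabolicModel, policy: CurrencyPolicy | None = None
) -> ModelGraph:
    """Bipartite graph: metabolite and reaction nodes, edge iff nonzero coefficient.

    Metabolite nodes are labeled with their compartment-stripped base id (so
    the same species in different models/compartments matches); reaction
    nodes with the reaction id. Currency metabolites (per ``policy``) are
    removed together with their incident edges; isolated nodes remain.
    """
    policy = policy if policy is not None else CurrencyPolicy()
    base = {m.id: strip_compartment(m.id) for m in model.metabolites}
    currency = set(policy.ids)
    removed = {mid for mid, b in base.items() if b in currency}
    if policy.degree_threshold is not None:
        degree = Counter()
        for r in model.reactions:
            for mid in r.stoichiometry:
                degree[mid] += 1
        removed |= {mid for mid, d in degree.items() if d > policy.degree_threshold}

    labels: dict[str, str] = {}
    adjacency: dict[str, list[str]] = {}
    for m in model.metabolites:
        if m.id in removed:
            continue
        node = f"m:{m.id}"
        labels[node] = base[m.id]
        adjacency[node] = []
    for r in model.reactions:
        node = f"r:{r.id}"
        labels[node] = r.id
        adjacency[node] = []
        for mid in r.stoichiometry:
            if mid in removed:
                continue
            mnode = f"m:{mid}"
            adjacency[node].append(mnode)
            adjacency[mnode].append(node)
    for node in adjacency:
        adjacency[node].sort()
    return ModelGraph(labels, adjacency)


def _wl_feature_counts(graphs: Sequence[ModelGraph], h: int) -> list[Counter]:
    """WL refinement feature counts for each graph, with one shared label dictionary.

    Feature keys are (iteration, compressed label); compressed labels are
    drawn from a shared injective dictionary over (own label, sorted neighbor
    labels), so identical subtree patterns always map to the same key and
    distinct patterns never collide.
    """
    if h < 0:
        raise ValueError("number of WL iterations h must be >= 0")
    counts = [Counter() for _ in graphs]
    current = [dict(g.labels) for g in graphs]
    for gi, lab in enumerate(current):
        for v in lab.values():
            counts[gi][(0, v)] += 1
    for it in range(1, h + 1):
        compress: dict[tuple, int] = {}
        new = []
        for gi, g in enumerate(graphs):
            lab = current[gi]
            nxt = {}
            for node in g.labels:
                signature = (lab[node], tuple(sorted(lab[u] for u in g.adjacency[node])))
                code = compress.setdefault(signature, len(compress))
                nxt[node] = code
                counts[gi][(it, code)] += 1
            new.append(nxt)
        current = new
    return counts


def wls_kernel(gA: ModelGraph, gB: ModelGraph, h: int = 3) -> int:
    """Weisfeiler-Lehman subtree kernel value (exact integer dot product)."""
    cA, cB = _wl_feature_counts([gA, gB], h)
    common = cA.keys() & cB.keys()
    return int(sum(cA[key] * cB[key] for key in common))


def wls_distance_matrix(
    models: Sequence[MetabolicModel],
    policy: CurrencyPolicy | None = None,
    h: int = 3,
) -> DistanceMatrix:
    """Cosine-normalized WLS kernel distance 1 − k(x,y)/√(k(x,x)·k(y,y))."""
    if len(models) < 2:
        raise ValueError("need at least 2 models")
    graphs = [build_model_graph(m, policy) for m in models]
    counts = _wl_feature_counts(graphs, h)
    n = len(models)
    K = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            common = counts[i].keys() & counts[j].keys()
            K[i, j] = K[j, i] = sum(counts[i][key] * counts[j][key] for key in common)
    diag = np.diag(K)
    empty = np.where(diag == 0)[0]
    if empty.size:
        bad = [models[i].id for i in empty]
        raise ValidationError(f"models with empty graphs (self-kernel 0): {bad}")
    D = 1.0 - K / np.sqrt(np.outer(diag, diag))
    D = np.clip(D, 0.0, 1.0)
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix([m.id for m in models], D, "wls")
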