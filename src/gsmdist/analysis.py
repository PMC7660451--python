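"""Embedding, metric comparison, and differential-activity screening.

* :func:`kernel_pca` embeds a distance matrix into Cartesian coordinates via
  Gower double-centering of the squared distances (classical
  multidimensional scaling — the standard kernel-PCA construction when only
  pairwise distances are available). Negative eigenvalues, which arise when a
  distance matrix is not Euclidean, are truncated and their total magnitude
  reported.
* :func:`trajectories` turns paired models (e.g., the same subject before and
  after an intervention) into displacement vectors in the embedding.
* :func:`mantel` is the permutation test for correlation between two distance
  matrices; it respects their dependence structure by jointly permuting the
  rows and columns of one matrix.
* :func:`kruskal_wallis_screen` runs the rank-based k-sample Kruskal-Wallis
  test per reaction column of a normalized flux matrix to find reactions
  whose activity differs between model groups. P-values are raw by default
  (p < alpha flags significance); Benjamini-Hochberg correction is optional.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .clustering import Labeling
from .metrics import DistanceMatrix
from .model import ValidationError
from .sampling import NormalizedFluxMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "Embedding",
    "Trajectory",
    "MantelResult",
    "ScreenResult",
    "kernel_pca",
    "trajectories",
    "mantel",
    "kruskal_wallis_screen",
    "pathway_counts",
    "flag_outlier_fluxes",
]


# ---------------------------------------------------------------------------
# kernel PCA / classical MDS
# ---------------------------------------------------------------------------


@dataclass
class Embedding:
    """Coordinates of each model in the metric space plus explained variance."""

    ids: list[str]
    coordinates: np.ndarray  # n × d
    explained_variance: np.ndarray  # d fractions of the positive spectrum
    negative_eigenvalue_mass: float = 0.0

    def coords_of(self, model_id: str) -> np.ndarray:
        return self.coordinates[self.ids.index(model_id)]


def kernel_pca(d: DistanceMatrix, n_components: int = 2) -> Embedding:
    """Embed a distance matrix by eigendecomposition of the Gower-centered matrix.

    Forms ``B = −½·H·(D∘D)·H`` with ``H = I − 11ᵀ/n``, keeps the top positive
    eigenvalues, and scales eigenvectors by √eigenvalue. Explained-variance
    fractions are relative to the sum of positive eigenvalues. For Euclidean
    distance matrices this reproduces classical MDS exactly.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    n = d.n
    D2 = d.values**2
    H = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * H @ D2 @ H
    B = (B + B.T) / 2.0
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(1e-12, 1e-9 * abs(eigval[0])) if n else 0.0
    positive = eigval > tol
    neg_mass = float(np.abs(eigval[eigval < -tol]).sum())
    n_pos = int(positive.sum())
    if n_components > n_pos:
        logger.warning(
            "requested %d components but only %d positive eigenvalues; truncating",
            n_components,
            n_pos,
        )
        n_components = n_pos
    if n_components == 0:
        return Embedding(list(d.ids), np.zeros((n, 1)), np.zeros(1), neg_mass)
    lam = eigval[:n_components]
    vec = eigvec[:, :n_components]
    # deterministic sign: largest-magnitude loading of each axis is positive
    for j in range(n_components):
        pivot = np.argmax(np.abs(vec[:, j]))
        if vec[pivot, j] < 0:
            vec[:, j] = -vec[:, j]
    coords = vec * np.sqrt(lam)
    explained = lam / eigval[positive].sum()
    return Embedding(list(d.ids), coords, explained, neg_mass)


@dataclass(frozen=True)
class Trajectory:
    """Displacement of one subject between two models in embedding space."""

    subject_id: str
    start_id: str
    end_id: str
    displacement: tuple[float, ...]

    @property
    def magnitude(self) -> float:
        return float(np.linalg.norm(self.displacement))


def trajectories(
    e: Embedding, pairs: Sequence[tuple[str, str, str]]
) -> list[Trajectory]:
    """Displacement vectors coords(end) − coords(start) for (start, end, subject) pairs."""
    out = []
    for start, end, subject in pairs:
        if start not in e.ids or end not in e.ids:
            missing = [x for x in (start, end) if x not in e.ids]
            raise KeyError(f"model ids not in embedding: {missing}")
        disp = e.coords_of(end) - e.coords_of(start)
        out.append(Trajectory(subject, start, end, tuple(float(x) for x in disp)))
    return out


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MantelResult:
    r: float
    p_value: float
    n_permutations: int
    seed: int


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_permutations: int = 9999,
    seed: int = 0,
) -> MantelResult:
    """Permutation test of the Pearson correlation between two distance matrices.

    The observed statistic is the correlation of the strictly-upper-triangle
    entries; the null distribution jointly permutes rows and columns of the
    second matrix. Two-sided p-value with the add-one convention
    ``p = (1 + #{|r*| ≥ |r|}) / (1 + n_permutations)``.
    """
    if d1.ids != d2.ids:
        raise ValidationError("distance matrices are over different (or reordered) model ids")
    n = d1.n
    if n < 4:
        raise ValueError("Mantel test needs at least 4 models")
    iu = np.triu_indices(n, k=1)
    x = d1.values[iu]
    y = d2.values[iu]
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in a distance matrix upper triangle")
    xc = (x - x.mean()) / x.std()

    def corr_with(mat: np.ndarray) -> float:
        v = mat[iu]
        return float(np.mean(xc * (v - v.mean()) / v.std()))

    r_obs = corr_with(d2.values)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        r_perm = corr_with(d2.values[np.ix_(perm, perm)])
        if abs(r_perm) >= abs(r_obs) - 1e-15:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return MantelResult(r_obs, p, n_permutations, seed)


# ---------------------------------------------------------------------------
# Kruskal-Wallis screen
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScreenResult:
    reaction_id: str
    statistic: float
    p_value: float
    significant: bool
    subsystem: str = ""


def kruskal_wallis_screen(
    nfm: NormalizedFluxMatrix,
    labels: Labeling,
    alpha: float = 0.05,
    bh_correction: bool = False,
) -> list[ScreenResult]:
    """Per-reaction Kruskal-Wallis test between model groups, sorted by p-value.

    Uses the tie-corrected H statistic with a chi-square reference law
    (groups − 1 degrees of freedom). Significance is raw ``p < alpha`` by
    default; with ``bh_correction`` the Benjamini-Hochberg adjusted p-values
    are thresholded instead. A column whose values are all tied gets H = 0,
    p = 1 by convention. Every group must contain at least 2 models.
    """
    arr = labels.array(nfm.model_ids)
    groups = np.unique(arr)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    counts = {g: int((arr == g).sum()) for g in groups}
    small = [int(g) for g, c in counts.items() if c < 2]
    if small:
        raise ValueError(f"groups with fewer than 2 models: {small}")

    stats_p: list[tuple[str, float, float]] = []
    for j, rid in enumerate(nfm.reaction_ids):
        col = nfm.values[:, j]
        samples = [col[arr == g] for g in groups]
        if np.ptp(col) == 0:
            H, p = 0.0, 1.0
        else:
            H, p = stats.kruskal(*samples)
        stats_p.append((rid, float(H), float(p)))

    pvals = np.array([p for _, _, p in stats_p])
    if bh_correction:
        adjusted = _benjamini_hochberg(pvals)
        signif = adjusted < alpha
    else:
        signif = pvals < alpha
    results = [
        ScreenResult(rid, H, p, bool(s), nfm.subsystems.get(rid, ""))
        for (rid, H, p), s in zip(stats_p, signif)
    ]
    return sorted(results, key=lambda r: (r.p_value, r.reaction_id))


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    adjusted = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, p[idx] * m / rank)
        adjusted[idx] = running
    return adjusted


def pathway_counts(results: Sequence[ScreenResult]) -> dict[str, int]:
    """Significant reactions per subsystem, sorted by descending count."""
    counts: dict[str, int] = {}
    for r in results:
        if not r.significant:
            continue
        key = r.subsystem or "unannotated"
        counts[key] = counts.get(key, 0) + 1
    return dict(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))


def flag_outlier_fluxes(
    nfm: NormalizedFluxMatrix, threshold: float = 2.5
) -> list[tuple[str, str, float]]:
    """All (model, reaction, z) entries with |z| above the threshold (default ±2.5σ)."""
    rows, cols = np.where(np.abs(nfm.values) > threshold)
    return [
        (nfm.model_ids[i], nfm.reaction_ids[j], float(nfm.values[i, j]))
        for i, j in zip(rows, cols)
    ]
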