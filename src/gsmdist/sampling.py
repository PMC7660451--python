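"""Flux sampling and the flux-correlation distance.

The third workflow metric compares models by the *behavior* of their
metabolic networks rather than their content: each model's steady-state flux
polytope ``{v : S·v = 0, lb ≤ v ≤ ub}`` is sampled uniformly, the samples are
averaged into a per-model mean flux vector, the vectors are stacked over the
template reaction universe (reactions absent from a model contribute 0, with
an absence mask retained), columns are z-scored across models, and the
distance between two models is ``1 − |Pearson r|`` between their normalized
flux rows. Sampling, rather than flux-balance optimization, is used because
an FBA optimum is a single arbitrary vertex of a highly degenerate polytope,
whereas the sample mean summarizes the whole solution space without
committing to an objective.

The sampler is a hit-and-run chain on the null-space parameterization of the
steady-state constraint: a feasible point is found by LP, movement is
restricted to ``v0 + null(S)·u``, and each step samples uniformly along a
random chord of the bounded polytope. Warm-up steps and thinning decorrelate
the chain; the stationary law is exactly uniform on the polytope. All
randomness flows through a single integer seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import null_space
from scipy.optimize import linprog

from .io import ReactionUniverse
from .metrics import DistanceMatrix
from .model import MetabolicModel, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "MediumSpec",
    "FluxMatrix",
    "NormalizedFluxMatrix",
    "InfeasibleModelError",
    "apply_medium",
    "sample_polytope",
    "sample_mean_flux",
    "build_flux_matrix",
    "normalize_flux_matrix",
    "flux_distance_matrix",
    "BOUND_CAP",
]

#: Magnitude at which infinite flux bounds are capped so the polytope is
#: bounded (standard constraint-based-modeling convention, mmol·gDW⁻¹·h⁻¹).
BOUND_CAP = 1000.0


class InfeasibleModelError(ValueError):
    """The steady-state polytope of one or more models is empty."""


# ---------------------------------------------------------------------------
# medium application
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MediumSpec:
    """Exchange-reaction uptake limits (uptake magnitudes, non-negative)."""

    uptakes: dict[str, float]

    def __post_init__(self) -> None:
        for rid, mag in self.uptakes.items():
            if mag < 0:
                raise ValueError(f"medium uptake for {rid!r} must be >= 0, got {mag}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MediumSpec":
        frame = pd.read_csv(path, sep="\t")
        return cls(dict(zip(frame.iloc[:, 0].astype(str), frame.iloc[:, 1].astype(float))))

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        pd.DataFrame(
            sorted(self.uptakes.items()), columns=["exchange_id", "uptake"]
        ).to_csv(path, sep="\t", index=False)
        return path


def apply_medium(model: MetabolicModel, medium: MediumSpec) -> MetabolicModel:
    """Constrain exchange uptake bounds to a medium; returns a new model.

    Convention: negative exchange flux is uptake. Listed exchanges get
    ``lower_bound = −uptake``; every other exchange gets ``lower_bound = 0``
    (uptake closed); upper bounds (secretion) are untouched. Medium entries
    naming a reaction the model lacks are skipped with a warning (model sets
    differ in their exchanges); naming a non-exchange reaction is an error.
    """
    from dataclasses import replace

    out = model.copy()
    exchange_ids = {r.id for r in out.reactions if r.is_exchange}
    for rid in medium.uptakes:
        if rid in exchange_ids:
            continue
        if rid in set(out.reaction_ids):
            raise ValidationError(
                f"medium entry {rid!r} is not an exchange reaction of model {model.id!r}"
            )
        logger.warning("medium entry %r absent from model %r; skipped", rid, model.id)
    new_reactions = []
    for r in out.reactions:
        if r.is_exchange:
            uptake = medium.uptakes.get(r.id, 0.0)
            new_lb = min(-uptake, r.upper_bound)
            r = replace(r, lower_bound=new_lb)
        new_reactions.append(r)
    out.reactions = new_reactions
    return out


# ---------------------------------------------------------------------------
# polytope sampling
# ---------------------------------------------------------------------------


def _feasible_point(S: np.ndarray, lb: np.ndarray, ub: np.ndarray) -> np.ndarray | None:
    n = len(lb)
    kwargs = {}
    if S.size:
        kwargs = {"A_eq": S, "b_eq": np.zeros(S.shape[0])}
    res = linprog(np.zeros(n), bounds=list(zip(lb, ub)), method="highs", **kwargs)
    if res.status != 0:
        return None
    v0 = np.asarray(res.x, float)
    if S.size:
        # refine onto the null space of S (LP solutions satisfy S·v=0 only to
        # solver tolerance)
        correction, *_ = np.linalg.lstsq(S, S @ v0, rcond=None)
        v0 = v0 - correction
    return np.clip(v0, lb, ub)


def sample_polytope(
    S: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    n_samples: int,
    seed: int,
    warmup_per_dim: int = 100,
    thinning: int = 15,
) -> np.ndarray:
    """Approximately uniform samples from ``{v : S·v = 0, lb ≤ v ≤ ub}``.

    Hit-and-run on the null-space parameterization: from the current point, a
    direction is drawn isotropically inside the null space of S, the feasible
    chord along it is computed from the bounds, and the next point is uniform
    on that chord. The stationary law of this chain is exactly uniform on the
    polytope. ``warmup_per_dim · dim`` burn-in steps precede sampling and
    ``thinning`` chain steps separate retained samples. Deterministic given
    ``seed``.
    """
    S = np.asarray(S, float)
    lb = np.asarray(lb, float)
    ub = np.asarray(ub, float)
    n = len(lb)
    lb = np.clip(lb, -BOUND_CAP, BOUND_CAP)
    ub = np.clip(ub, -BOUND_CAP, BOUND_CAP)
    v0 = _feasible_point(S, lb, ub)
    if v0 is None:
        raise InfeasibleModelError("steady-state polytope is empty")
    if S.size:
        N = null_space(S)
    else:
        N = np.eye(n)
    dim = N.shape[1]
    if dim == 0:
        return np.tile(v0, (n_samples, 1))

    rng = np.random.default_rng(seed)
    v = v0.copy()
    tol = 1e-11

    def step(direction_v: np.ndarray) -> None:
        nonlocal v
        norm = np.linalg.norm(direction_v)
        if norm < tol:
            return
        w = direction_v / norm
        with np.errstate(divide="ignore", invalid="ignore"):
            lo = (lb - v) / w
            hi = (ub - v) / w
        active = np.abs(w) > tol
        if not active.any():
            return
        tmin = np.max(np.minimum(lo, hi)[active])
        tmax = np.min(np.maximum(lo, hi)[active])
        if not tmax - tmin > 0:  # empty or zero-length chord (vertex / point polytope)
            return
        t = rng.uniform(tmin, tmax)
        v = np.clip(v + t * w, lb, ub)

    for _ in range(warmup_per_dim * dim):
        step(N @ rng.standard_normal(dim))

    samples = np.empty((n_samples, n), float)
    for i in range(n_samples):
        for _ in range(thinning):
            step(N @ rng.standard_normal(dim))
        samples[i] = v
    return samples


def sample_mean_flux(
    model: MetabolicModel,
    n_samples: int = 1000,
    seed: int = 0,
    thinning: int = 15,
) -> np.ndarray:
    """Coordinate-wise mean of uniform samples of the model's flux polytope.

    Vector is ordered like ``model.reactions``. Raises
    :class:`InfeasibleModelError` when the polytope is empty.
    """
    S, _, _ = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    try:
        samples = sample_polytope(S, lb, ub, n_samples, seed, thinning=thinning)
    except InfeasibleModelError as exc:
        raise InfeasibleModelError(f"model {model.id!r}: {exc}") from exc
    return samples.mean(axis=0)


# ---------------------------------------------------------------------------
# flux matrices
# ---------------------------------------------------------------------------


@dataclass
class FluxMatrix:
    """Models × universe-reactions matrix of mean sampled fluxes.

    ``mask[i, j]`` is True when universe reaction j is absent from model i (the
    stored flux there is 0 by convention, so all models share one column
    space).
    """

    model_ids: list[str]
    reaction_ids: list[str]
    values: np.ndarray
    mask: np.ndarray
    n_samples: int
    seed: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        self.mask = np.asarray(self.mask, bool)
        shape = (len(self.model_ids), len(self.reaction_ids))
        if self.values.shape != shape or self.mask.shape != shape:
            raise ValidationError("flux matrix shape mismatch")
        if not np.isfinite(self.values).all():
            raise ValidationError("flux matrix contains non-finite values")

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        frame = pd.DataFrame(self.values, index=self.model_ids, columns=self.reaction_ids)
        frame.to_csv(path, sep="\t", index_label="model_id", float_format="%.12g")
        return path


@dataclass
class NormalizedFluxMatrix:
    """Column-wise z-scored flux matrix; zero-variance columns dropped."""

    model_ids: list[str]
    reaction_ids: list[str]
    values: np.ndarray
    dropped: list[str]
    mask: np.ndarray
    subsystems: dict[str, str] = field(default_factory=dict)

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        frame = pd.DataFrame(self.values, index=self.model_ids, columns=self.reaction_ids)
        frame.to_csv(path, sep="\t", index_label="model_id", float_format="%.12g")
        return path


def derive_seeds(master_seed: int, n: int, stage: str = "") -> list[int]:
    """Deterministic per-item seeds fanned out from one master seed."""
    import zlib

    ss = np.random.SeedSequence(master_seed, spawn_key=(zlib.crc32(stage.encode()) % (2**31),))
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def build_flux_matrix(
    models: Sequence[MetabolicModel],
    universe: ReactionUniverse,
    medium: MediumSpec | None = None,
    n_samples: int = 1000,
    seed: int = 0,
    thinning: int = 15,
) -> FluxMatrix:
    """Stack per-model mean sampled fluxes over the universe columns.

    Per-model sampler seeds are derived deterministically from ``seed``.
    Infeasible models are reported together in one error.
    """
    import zlib

    constrained = [apply_medium(m, medium) if medium is not None else m for m in models]
    idx = universe.index()
    # seed per model from (master seed, model id): identical models get
    # identical chains, and rows do not depend on the order of the model list
    seeds = [
        int(
            np.random.SeedSequence([seed, zlib.crc32(m.id.encode())])
            .generate_state(1)[0] % (2**31)
        )
        for m in models
    ]
    values = np.zeros((len(models), len(universe)))
    mask = np.ones((len(models), len(universe)), bool)
    infeasible = []
    for i, m in enumerate(constrained):
        try:
            mean_flux = sample_mean_flux(m, n_samples=n_samples, seed=seeds[i], thinning=thinning)
        except InfeasibleModelError:
            infeasible.append(m.id)
            continue
        for j, rid in enumerate(m.reaction_ids):
            col = idx.get(rid)
            if col is not None:
                values[i, col] = mean_flux[j]
                mask[i, col] = False
    if infeasible:
        raise InfeasibleModelError(f"infeasible models: {infeasible}")
    return FluxMatrix(
        [m.id for m in models], list(universe.ids), values, mask, n_samples, seed
    )


def normalize_flux_matrix(
    fm: FluxMatrix, subsystems: Mapping[str, str] | None = None
) -> NormalizedFluxMatrix:
    """Z-score each column across models (sample sd); drop zero-variance columns."""
    if len(fm.model_ids) < 2:
        raise ValueError("need at least 2 models to normalize")
    mean = fm.values.mean(axis=0)
    sd = fm.values.std(axis=0, ddof=1)
    keep = sd > 0
    dropped = [rid for rid, k in zip(fm.reaction_ids, keep) if not k]
    values = (fm.values[:, keep] - mean[keep]) / sd[keep]
    kept_ids = [rid for rid, k in zip(fm.reaction_ids, keep) if k]
    subs = {rid: (subsystems or {}).get(rid, "") for rid in kept_ids}
    return NormalizedFluxMatrix(
        list(fm.model_ids), kept_ids, values, dropped, fm.mask[:, keep], subs
    )


def flux_distance_matrix(nfm: NormalizedFluxMatrix) -> DistanceMatrix:
    """Distance 1 − |Pearson r| between normalized flux rows of model pairs."""
    if len(nfm.reaction_ids) < 2:
        raise ValueError("need at least 2 retained reaction columns")
    row_sd = nfm.values.std(axis=1)
    flat = [mid for mid, s in zip(nfm.model_ids, row_sd) if s == 0]
    if flat:
        raise ValidationError(f"models with zero flux variance across reactions: {flat}")
    corr = np.corrcoef(nfm.values)
    dist = 1.0 - np.abs(corr)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(dist, 0.0)
    return DistanceMatrix(list(nfm.model_ids), dist, "flux")
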