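"""Synthetic model families with planted structure.

Real model collections (microbial reconstructions, patient-derived tissue
models) are large downloads; this module generates small families of
constraint-based models that carry the same kinds of signal, so every stage
of the workflow is testable offline:

* a **shared linear core pathway** (uptake exchange → chain → sink exchange)
  present in every model;
* **shared side-chain modules** with their own uptake/sink exchanges, present
  in every model; a subset of them is *differential*: their flux bounds are
  scaled by ``1 ± flux_effect`` depending on the group, planting a
  group-specific flux signal that stays local to those columns (the remaining
  side chains are true nulls for screen calibration);
* **group-specific branch modules** re-using core metabolites, which encode
  the cluster structure in reaction content; individual module reactions flip
  presence with probability ``inclusion_noise``;
* **per-model bound jitter**: every model rescales each reaction's bound
  magnitudes by an independent factor ``1 ± bound_jitter·U``, emulating the
  individual variability of patient-derived reconstructions — without it the
  only within-group variation in sampled fluxes would be Monte-Carlo noise,
  which is not exchangeable across structurally different models.

Every emitted model keeps ``lb ≤ 0 ≤ ub`` on all reactions, so the zero flux
vector is always feasible and the LP feasibility check can never fail. All
generation is deterministic given the spec seed. Networks are kept small
(≤ ~60 reactions) so polytope centroids can be verified exactly in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .clustering import Labeling
from .model import MetabolicModel, Metabolite, Reaction

__all__ = ["SyntheticSpec", "GroundTruth", "generate_family", "template_model", "generate_expression"]

_COMPARTMENT = "c"
_BASE_FLUX = 10.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic model family.

    Defaults mirror a two-condition paired study: 2 groups × 12 models, a
    core chain of 10 reactions, 3 group-specific modules of 4 reactions, 5%
    inclusion noise, and a ±50% relative bound perturbation on the planted
    differential side chains.
    """

    n_groups: int = 2
    models_per_group: int = 12
    core_length: int = 10
    modules_per_group: int = 3
    module_size: int = 4
    inclusion_noise: float = 0.05
    flux_effect: float = 0.5
    shared_modules: int = 6
    n_differential: int = 3
    bound_jitter: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.inclusion_noise <= 1:
            raise ValueError("inclusion_noise must be in [0, 1]")
        if not 0 <= self.bound_jitter < 1:
            raise ValueError("bound_jitter must be in [0, 1)")
        if self.flux_effect < 0:
            raise ValueError("flux_effect must be >= 0")
        for name in ("n_groups", "models_per_group", "core_length", "modules_per_group", "module_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_differential > self.shared_modules:
            raise ValueError("n_differential cannot exceed shared_modules")


@dataclass
class GroundTruth:
    """Planted structure of a generated family."""

    labeling: Labeling
    differential_reactions: list[str]
    class_labels: dict[str, str]
    group_module_genes: dict[int, list[str]] = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        frame = pd.DataFrame(
            sorted(self.labeling.labels.items()), columns=["model_id", "group"]
        )
        frame["class_label"] = [self.class_labels[m] for m in frame["model_id"]]
        frame.to_csv(path, sep="\t", index=False)


def _exchange(rid: str, met: str, lb: float, ub: float, subsystem: str) -> Reaction:
    return Reaction(rid, {met: -1.0}, lb, ub, gene_rule="", subsystem=subsystem)


def _internal(rid: str, sub: str, stoich: dict[str, float], ub: float) -> Reaction:
    return Reaction(rid, stoich, 0.0, ub, gene_rule=f"g_{rid}", subsystem=sub)


def _group_scale(group: int, n_groups: int, flux_effect: float) -> float:
    if n_groups == 1:
        return 1.0
    # evenly spread factors 1+fe .. 1-fe across groups
    return 1.0 + flux_effect * (1.0 - 2.0 * group / (n_groups - 1))


def _core_parts(spec: SyntheticSpec) -> tuple[list[Metabolite], list[Reaction]]:
    mets = [Metabolite(f"C{j}_{_COMPARTMENT}", _COMPARTMENT) for j in range(spec.core_length + 1)]
    rxns = [_exchange("EX_core_in", mets[0].id, -_BASE_FLUX, 0.0, "Core pathway")]
    for j in range(spec.core_length):
        rxns.append(
            _internal(
                f"R_core_{j}", "Core pathway",
                {mets[j].id: -1.0, mets[j + 1].id: 1.0}, _BASE_FLUX,
            )
        )
    rxns.append(_exchange("EX_core_out", mets[-1].id, 0.0, _BASE_FLUX, "Core pathway"))
    return mets, rxns


def _shared_module(m: int) -> tuple[list[Metabolite], list[Reaction]]:
    sub = f"Flux module {m}"
    a = Metabolite(f"F{m}a_{_COMPARTMENT}", _COMPARTMENT)
    b = Metabolite(f"F{m}b_{_COMPARTMENT}", _COMPARTMENT)
    rxns = [
        _exchange(f"EX_F{m}_in", a.id, -_BASE_FLUX, 0.0, sub),
        _internal(f"FR_{m}", sub, {a.id: -1.0, b.id: 1.0}, _BASE_FLUX),
        _exchange(f"EX_F{m}_out", b.id, 0.0, _BASE_FLUX, sub),
    ]
    return [a, b], rxns


def _group_module(
    group: int, q: int, core_mets: list[Metabolite], module_size: int
) -> tuple[list[Metabolite], list[Reaction]]:
    sub = f"Group {group} module {q}"
    anchor = core_mets[1 + (group * 7 + q * 3) % (len(core_mets) - 2)]
    mets = [
        Metabolite(f"G{group}q{q}n{i}_{_COMPARTMENT}", _COMPARTMENT)
        for i in range(module_size)
    ]
    rxns = [
        _internal(f"GR_{group}_{q}_0", sub, {anchor.id: -1.0, mets[0].id: 1.0}, _BASE_FLUX)
    ]
    for i in range(1, module_size):
        rxns.append(
            _internal(
                f"GR_{group}_{q}_{i}", sub,
                {mets[i - 1].id: -1.0, mets[i].id: 1.0}, _BASE_FLUX,
            )
        )
    rxns.append(_exchange(f"EX_G{group}_{q}", mets[-1].id, 0.0, _BASE_FLUX, sub))
    return mets, rxns


def _scale_bounds(r: Reaction, factor: float) -> Reaction:
    return replace(r, lower_bound=r.lower_bound * factor, upper_bound=r.upper_bound * factor)


def template_model(spec: SyntheticSpec) -> MetabolicModel:
    """The 'parent' model: union of core, shared and all group modules, base bounds."""
    core_mets, core_rxns = _core_parts(spec)
    mets, rxns = list(core_mets), list(core_rxns)
    for m in range(spec.shared_modules):
        mm, rr = _shared_module(m)
        mets += mm
        rxns += rr
    for g in range(spec.n_groups):
        for q in range(spec.modules_per_group):
            mm, rr = _group_module(g, q, core_mets, spec.module_size)
            mets += mm
            rxns += rr
    genes = sorted({gene for r in rxns for gene in r.genes})
    return MetabolicModel("template", rxns, mets, genes).validate()


def generate_family(spec: SyntheticSpec) -> tuple[list[MetabolicModel], GroundTruth]:
    """Generate a model family with planted groups and flux differences."""
    rng = np.random.default_rng(spec.seed)
    core_mets, core_rxns = _core_parts(spec)
    shared = [_shared_module(m) for m in range(spec.shared_modules)]
    group_mods = {
        g: [_group_module(g, q, core_mets, spec.module_size) for q in range(spec.modules_per_group)]
        for g in range(spec.n_groups)
    }
    differential = sorted(
        r.id for m in range(spec.n_differential) for r in shared[m][1]
    )

    models = []
    labels: dict[str, int] = {}
    class_labels: dict[str, str] = {}
    for g in range(spec.n_groups):
        factor = _group_scale(g, spec.n_groups, spec.flux_effect)
        for i in range(spec.models_per_group):
            model_id = f"G{g}_M{i:02d}"
            mets = list(core_mets)
            rxns = list(core_rxns)
            for m, (mm, rr) in enumerate(shared):
                mets += mm
                scale = factor if m < spec.n_differential else 1.0
                rxns += [_scale_bounds(r, scale) for r in rr]
            for gg in range(spec.n_groups):
                own = gg == g
                for mm, rr in group_mods[gg]:
                    flips = rng.random(len(rr)) < spec.inclusion_noise
                    included = [r for r, flip in zip(rr, flips) if own != flip]
                    if included:
                        rxns += included
                        needed = {mid for r in included for mid in r.stoichiometry}
                        mets += [m_ for m_ in mm if m_.id in needed]
            if spec.bound_jitter:
                # individual variability: each model perturbs every reaction's
                # bound magnitudes independently (groups stay exchangeable)
                rxns = [
                    _scale_bounds(r, 1.0 + spec.bound_jitter * (2.0 * rng.random() - 1.0))
                    for r in rxns
                ]
            genes = sorted({gene for r in rxns for gene in r.genes})
            model = MetabolicModel(
                model_id, rxns, _dedupe(mets), genes, class_label=f"group{g}"
            ).validate()
            models.append(model)
            labels[model_id] = g
            class_labels[model_id] = f"group{g}"

    group_genes = {
        g: sorted({gene for _, rr in group_mods[g] for r in rr for gene in r.genes})
        for g in range(spec.n_groups)
    }
    truth = GroundTruth(Labeling(labels), differential, class_labels, group_genes)
    return models, truth


def _dedupe(mets: list[Metabolite]) -> list[Metabolite]:
    seen: dict[str, Metabolite] = {}
    for m in mets:
        seen.setdefault(m.id, m)
    return list(seen.values())


def generate_expression(
    models: list[MetabolicModel],
    ground_truth: GroundTruth,
    seed: int = 0,
    shift: float = 2.0,
    duplicate_fraction: float = 0.2,
) -> dict[str, pd.DataFrame]:
    """Per-model expression tables (columns gene, intensity) with planted shifts.

    Intensities are log-normal; genes of a model's own group modules are
    shifted upward by ``shift`` in log2 space so expression-based confidence
    scoring can be validated against the planted structure. A
    ``duplicate_fraction`` of genes is emitted as two probes to exercise
    probe averaging.
    """
    rng = np.random.default_rng(seed)
    tables: dict[str, pd.DataFrame] = {}
    for model in models:
        group = ground_truth.labeling.labels[model.id]
        own_genes = set(ground_truth.group_module_genes.get(group, []))
        rows: list[tuple[str, float]] = []
        for gene in model.genes:
            log2_mean = 6.0 + (shift if gene in own_genes else 0.0)
            n_probes = 2 if rng.random() < duplicate_fraction else 1
            for _ in range(n_probes):
                rows.append((gene, float(2.0 ** rng.normal(log2_mean, 1.0))))
        tables[model.id] = pd.DataFrame(rows, columns=["gene", "intensity"])
    return tables
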