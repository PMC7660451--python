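"""Core domain types for constraint-based metabolic models.

A :class:`MetabolicModel` is a lightweight container for the three pieces of
information a genome-scale metabolic model (GSMM) carries: the reaction
network (stoichiometry), the flux bounds, and the gene-protein-reaction (GPR)
rules. It deliberately stores only what the distance workflow needs; full
SBML fidelity lives in :mod:`gsmdist.io`, which converts to and from cobrapy
models.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "ValidationError",
]


class ValidationError(ValueError):
    """A model violates a structural invariant."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    compartment: str
    name: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("metabolite id must be non-empty")
        if not self.compartment:
            raise ValidationError(f"metabolite {self.id!r}: compartment must be non-empty")


@dataclass(frozen=True)
class Reaction:
    """A (possibly reversible) biochemical reaction with flux bounds.

    Stoichiometry maps metabolite ids to signed coefficients (negative =
    consumed). Bounds are in mmol·gDW⁻¹·h⁻¹. ``gene_rule`` is a boolean
    expression over gene ids ("g1 and (g2 or g3)"); empty means no genetic
    evidence is associated with the reaction.
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    gene_rule: str = ""
    subsystem: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("reaction id must be non-empty")
        if self.lower_bound > self.upper_bound:
            raise ValidationError(
                f"reaction {self.id!r}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )

    @property
    def is_exchange(self) -> bool:
        """True iff the reaction involves exactly one metabolite (boundary)."""
        return len(self.stoichiometry) == 1

    @property
    def genes(self) -> frozenset[str]:
        """Gene ids mentioned in the GPR rule."""
        if not self.gene_rule:
            return frozenset()
        from cobra.core.gene import GPR

        return frozenset(GPR.from_string(self.gene_rule).genes)


@dataclass
class MetabolicModel:
    id: str
    reactions: list[Reaction] = field(default_factory=list)
    metabolites: list[Metabolite] = field(default_factory=list)
    genes: list[str] = field(default_factory=list)
    class_label: str | None = None

    def validate(self) -> "MetabolicModel":
        """Check structural invariants; return self for chaining."""
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            dup = sorted({r for r in rxn_ids if rxn_ids.count(r) > 1})
            raise ValidationError(f"model {self.id!r}: duplicate reaction ids {dup}")
        met_ids = {m.id for m in self.metabolites}
        if len(met_ids) != len(self.metabolites):
            raise ValidationError(f"model {self.id!r}: duplicate metabolite ids")
        gene_set = set(self.genes)
        for r in self.reactions:
            missing = set(r.stoichiometry) - met_ids
            if missing:
                raise ValidationError(
                    f"model {self.id!r}: reaction {r.id!r} references undeclared "
                    f"metabolites {sorted(missing)}"
                )
            missing_genes = r.genes - gene_set
            if missing_genes:
                raise ValidationError(
                    f"model {self.id!r}: reaction {r.id!r} GPR mentions unlisted "
                    f"genes {sorted(missing_genes)}"
                )
        return self

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def get_reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(rxn_id)

    def stoichiometric_matrix(self) -> tuple[np.ndarray, list[str], list[str]]:
        """Dense S matrix (metabolites × reactions) plus row/column ids."""
        met_ids = [m.id for m in self.metabolites]
        met_index = {m: i for i, m in enumerate(met_ids)}
        rxn_ids = self.reaction_ids
        S = np.zeros((len(met_ids), len(rxn_ids)))
        for j, r in enumerate(self.reactions):
            for met, coef in r.stoichiometry.items():
                S[met_index[met], j] = coef
        return S, met_ids, rxn_ids

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions], float)
        ub = np.array([r.upper_bound for r in self.reactions], float)
        return lb, ub

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            reactions=[replace(r, stoichiometry=dict(r.stoichiometry)) for r in self.reactions],
            metabolites=list(self.metabolites),
            genes=list(self.genes),
            class_label=self.class_label,
        )

    def __eq__(self, other: object) -> bool:
        """Field-level equality up to reaction/metabolite/gene ordering."""
        if not isinstance(other, MetabolicModel):
            return NotImplemented
        return (
            self.id == other.id
            and self.class_label == other.class_label
            and sorted(self.genes) == sorted(other.genes)
            and sorted(self.metabolites, key=lambda m: m.id)
            == sorted(other.metabolites, key=lambda m: m.id)
            and sorted(self.reactions, key=lambda r: r.id)
            == sorted(other.reactions, key=lambda r: r.id)
        )
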