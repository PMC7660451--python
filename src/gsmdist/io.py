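"""Model input/output and template alignment.

Models are read and written in two formats:

* **SBML Level 3** (with FBC flux bounds and gene associations), delegated to
  cobrapy. Subsystem annotations and the optional class label travel through
  SBML ``<notes>`` key-value pairs, which cobrapy round-trips.
* A **flat JSON dialect**: a document with keys ``id``, ``reactions`` (each
  with ``id``, ``metabolites`` map, ``lower_bound``, ``upper_bound``,
  ``gene_rule``, ``subsystem``), ``metabolites``, ``genes`` and optional
  ``class_label``.

Alignment of a model set against a template ("parent") model is expressed as
binary presence vectors over the template's reaction universe, the input of
the Jaccard metric.
"""

from __future__ import annotations

import ast
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import MetabolicModel, Metabolite, Reaction, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ReactionUniverse",
    "PresenceVector",
    "read_model",
    "write_model",
    "build_universe",
    "presence_vector",
    "expression_to_confidence",
    "write_confidence_tsv",
    "HIGH",
    "LOW",
    "ABSENT",
]

# ---------------------------------------------------------------------------
# universe / presence vectors
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReactionUniverse:
    """Ordered reaction id list taken from a template model."""

    ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError("universe reaction ids must be unique")

    def __len__(self) -> int:
        return len(self.ids)

    def index(self) -> dict[str, int]:
        return {r: i for i, r in enumerate(self.ids)}


@dataclass(frozen=True)
class PresenceVector:
    """Binary vector over a ReactionUniverse marking reactions a model carries."""

    model_id: str
    bits: np.ndarray
    universe: ReactionUniverse

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits, dtype=np.uint8)
        if bits.ndim != 1 or len(bits) != len(self.universe):
            raise ValidationError(
                f"presence vector of {self.model_id!r} has length {len(bits)}, "
                f"universe has {len(self.universe)}"
            )
        if not np.isin(bits, (0, 1)).all():
            raise ValidationError("presence vector entries must be 0/1")
        object.__setattr__(self, "bits", bits)


def build_universe(template: MetabolicModel) -> ReactionUniverse:
    """Reaction universe = the template's reaction ids in template order."""
    template.validate()
    return ReactionUniverse(tuple(template.reaction_ids))


def presence_vector(
    model: MetabolicModel, universe: ReactionUniverse, strict: bool = True
) -> PresenceVector:
    """Binary vector: bit r = 1 iff universe reaction r is in the model.

    In strict mode (default) a model reaction missing from the universe is an
    error — contextualized models are expected to be subsets of the template.
    In lenient mode such reactions are dropped with a logged count.
    """
    idx = universe.index()
    bits = np.zeros(len(universe), dtype=np.uint8)
    off_universe = []
    for rid in model.reaction_ids:
        i = idx.get(rid)
        if i is None:
            off_universe.append(rid)
        else:
            bits[i] = 1
    if off_universe:
        if strict:
            raise ValidationError(
                f"model {model.id!r}: reactions not in universe: {off_universe}"
            )
        logger.warning(
            "model %r: dropped %d reactions not in universe (e.g. %r)",
            model.id,
            len(off_universe),
            off_universe[0],
        )
    return PresenceVector(model.id, bits, universe)


# ---------------------------------------------------------------------------
# SBML via cobrapy
# ---------------------------------------------------------------------------

_SUBSYSTEM_KEY = "SUBSYSTEM"
_CLASS_KEY = "CLASS_LABEL"


def _to_cobra(model: MetabolicModel):
    import cobra

    cm = cobra.Model(model.id)
    mets = {
        m.id: cobra.Metabolite(m.id, name=m.name, compartment=m.compartment)
        for m in model.metabolites
    }
    rxns = []
    for r in model.reactions:
        cr = cobra.Reaction(r.id)
        cr.lower_bound = r.lower_bound
        cr.upper_bound = r.upper_bound
        rxns.append((cr, r))
    cm.add_reactions([cr for cr, _ in rxns])
    for cr, r in rxns:
        cr.add_metabolites({mets[mid]: coef for mid, coef in r.stoichiometry.items()})
        if r.gene_rule:
            cr.gene_reaction_rule = r.gene_rule
        if r.subsystem:
            cr.notes[_SUBSYSTEM_KEY] = r.subsystem
    if model.class_label is not None:
        cm.notes[_CLASS_KEY] = model.class_label
    return cm


def _from_cobra(cm) -> MetabolicModel:
    metabolites = [
        Metabolite(m.id, compartment=m.compartment or "c", name=m.name or "")
        for m in cm.metabolites
    ]
    reactions = []
    for r in cm.reactions:
        reactions.append(
            Reaction(
                id=r.id,
                stoichiometry={m.id: float(c) for m, c in r.metabolites.items()},
                lower_bound=float(r.lower_bound),
                upper_bound=float(r.upper_bound),
                gene_rule=r.gene_reaction_rule or "",
                subsystem=str(r.notes.get(_SUBSYSTEM_KEY, r.subsystem or "")),
            )
        )
    label = cm.notes.get(_CLASS_KEY)
    return MetabolicModel(
        id=cm.id or "model",
        reactions=reactions,
        metabolites=metabolites,
        genes=sorted(g.id for g in cm.genes),
        class_label=str(label) if label is not None else None,
    )


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------


def _model_to_json_dict(model: MetabolicModel) -> dict:
    return {
        "id": model.id,
        "class_label": model.class_label,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "metabolites": r.stoichiometry,
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gene_rule": r.gene_rule,
                "subsystem": r.subsystem,
            }
            for r in model.reactions
        ],
        "genes": list(model.genes),
    }


def _model_from_json_dict(doc: dict, source: str) -> MetabolicModel:
    try:
        metabolites = [
            Metabolite(m["id"], compartment=m["compartment"], name=m.get("name", ""))
            for m in doc.get("metabolites", [])
        ]
        reactions = [
            Reaction(
                id=r["id"],
                stoichiometry={k: float(v) for k, v in r["metabolites"].items()},
                lower_bound=float(r["lower_bound"]),
                upper_bound=float(r["upper_bound"]),
                gene_rule=r.get("gene_rule", ""),
                subsystem=r.get("subsystem", ""),
            )
            for r in doc.get("reactions", [])
        ]
        return MetabolicModel(
            id=doc["id"],
            reactions=reactions,
            metabolites=metabolites,
            genes=list(doc.get("genes", [])),
            class_label=doc.get("class_label"),
        )
    except (KeyError, TypeError) as exc:
        raise ValidationError(f"{source}: malformed JSON model document: {exc}") from exc


def read_model(path: str | Path, format: str | None = None) -> MetabolicModel:
    """Read a model from SBML or the flat JSON dialect.

    ``format`` may be ``"sbml"`` or ``"json"``; if omitted it is inferred from
    the file suffix (.xml/.sbml → SBML, .json → JSON).
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "sbml":
        import cobra

        try:
            cm = cobra.io.read_sbml_model(str(path))
        except Exception as exc:  # libsbml raises heterogeneous error types
            raise ValidationError(f"{path}: failed to parse SBML: {exc}") from exc
        return _from_cobra(cm).validate()
    if fmt == "json":
        try:
            doc = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ValidationError(f"{path}: failed to parse JSON: {exc}") from exc
        return _model_from_json_dict(doc, str(path)).validate()
    raise ValueError(f"unknown model format {fmt!r}")


def write_model(model: MetabolicModel, path: str | Path, format: str | None = None) -> Path:
    """Write a model so that ``read_model(write_model(m)) == m``."""
    path = Path(path)
    fmt = format or _infer_format(path)
    model.validate()
    if fmt == "sbml":
        import cobra

        cobra.io.write_sbml_model(_to_cobra(model), str(path))
    elif fmt == "json":
        path.write_text(json.dumps(_model_to_json_dict(model), indent=1, sort_keys=True))
    else:
        raise ValueError(f"unknown model format {fmt!r}")
    return path


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".xml", ".sbml"):
        return "sbml"
    if suffix == ".json":
        return "json"
    raise ValueError(f"cannot infer model format from suffix {suffix!r}")


# ---------------------------------------------------------------------------
# expression → reaction confidence
# ---------------------------------------------------------------------------

HIGH = "high"
LOW = "low"
ABSENT = "absent"
_RANK = {HIGH: 2, LOW: 1, ABSENT: 0}


def expression_to_confidence(
    expression: Mapping[str, float] | Iterable[tuple[str, float]] | pd.DataFrame,
    model: MetabolicModel,
    top_fraction: float = 0.30,
) -> dict[str, str]:
    """Map gene-expression intensities to per-reaction confidence classes.

    Intensities are log2-transformed; probes mapping to the same gene are
    averaged; genes in the top ``top_fraction`` of the transformed values are
    "high" confidence, the remaining measured genes "low", unmeasured genes
    "absent". Gene confidence propagates to reactions through the GPR rule
    with AND → minimum and OR → maximum over high > low > absent. Reactions
    whose rule mentions no measured gene are "absent". Because the ranking is
    what matters, the result is invariant under any strictly monotone
    rescaling of the raw intensities. Ties at the cutoff value are all
    included (rank-stable).

    ``expression`` may be a mapping gene → intensity, an iterable of
    (gene, intensity) probe pairs (genes may repeat), or a two-column
    DataFrame (gene, intensity).
    """
    if isinstance(expression, pd.DataFrame):
        pairs = list(expression.itertuples(index=False, name=None))
    elif isinstance(expression, Mapping):
        pairs = list(expression.items())
    else:
        pairs = list(expression)
    if not pairs:
        raise ValueError("empty expression table")
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must be in (0, 1)")
    for gene, value in pairs:
        if not (isinstance(value, (int, float)) and value > 0 and math.isfinite(value)):
            raise ValueError(f"non-positive or non-finite intensity for {gene!r}: {value}")

    df = pd.DataFrame(pairs, columns=["gene", "intensity"])
    df["log2"] = np.log2(df["intensity"].astype(float))
    per_gene = df.groupby("gene")["log2"].mean()

    n_top = max(1, int(math.ceil(top_fraction * len(per_gene))))
    ordered = per_gene.sort_values(ascending=False, kind="mergesort")
    cutoff = ordered.iloc[n_top - 1]
    high_genes = set(per_gene.index[per_gene >= cutoff])  # ties at cutoff included
    gene_conf = {g: (HIGH if g in high_genes else LOW) for g in per_gene.index}

    confidence: dict[str, str] = {}
    for r in model.reactions:
        confidence[r.id] = _rule_confidence(r.gene_rule, gene_conf)
    return confidence


def _rule_confidence(rule: str, gene_conf: Mapping[str, str]) -> str:
    if not rule:
        return ABSENT
    from cobra.core.gene import GPR

    tree = GPR.from_string(rule)
    if tree.body is None:
        return ABSENT

    def ev(node) -> int:
        if isinstance(node, ast.Name):
            return _RANK[gene_conf.get(node.id, ABSENT)]
        if isinstance(node, ast.BoolOp):
            vals = [ev(v) for v in node.values]
            return min(vals) if isinstance(node.op, ast.And) else max(vals)
        raise ValidationError(f"unsupported GPR node {ast.dump(node)}")

    rank = ev(tree.body)
    return {v: k for k, v in _RANK.items()}[rank]


def write_confidence_tsv(confidence: Mapping[str, str], path: str | Path) -> Path:
    path = Path(path)
    frame = pd.DataFrame(
        sorted(confidence.items()), columns=["reaction_id", "confidence"]
    )
    frame.to_csv(path, sep="\t", index=False)
    return path
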