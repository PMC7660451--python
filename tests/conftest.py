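import numpy as np
import pytest

from gsmdist import MetabolicModel, Metabolite, Reaction, SyntheticSpec, generate_family, template_model


@pytest.fixture
def chain_model() -> MetabolicModel:
    """EX_A → R1 → EX_B linear chain whose polytope is the segment t·(1,1,1), t∈[0,10]."""
    mets = [Metabolite("A", "c"), Metabolite("B", "c")]
    rxns = [
        Reaction("EX_A", {"A": 1.0}, 0.0, 10.0),
        Reaction("R1", {"A": -1.0, "B": 1.0}, 0.0, 10.0, gene_rule="g1", subsystem="Core"),
        Reaction("EX_B", {"B": -1.0}, 0.0, 10.0),
    ]
    return MetabolicModel("chain", rxns, mets, genes=["g1"]).validate()


@pytest.fixture(scope="session")
def default_family():
    """One synthetic 2×12 family with planted structure (deterministic)."""
    spec = SyntheticSpec(seed=11)
    models, truth = generate_family(spec)
    return spec, models, truth, template_model(spec)


def random_model(rng: np.random.Generator, model_id: str, universe_rxns=None) -> MetabolicModel:
    """Small random model: random subset of a shared 40-reaction universe."""
    spec = SyntheticSpec(seed=7)
    template = template_model(spec)
    keep = rng.random(len(template.reactions)) < 0.6
    rxns = [r for r, k in zip(template.reactions, keep) if k]
    needed = {mid for r in rxns for mid in r.stoichiometry}
    mets = [m for m in template.metabolites if m.id in needed]
    genes = sorted({g for r in rxns for g in r.genes})
    return MetabolicModel(model_id, rxns, mets, genes).validate()
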