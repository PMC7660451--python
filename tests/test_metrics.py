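"""Jaccard and Weisfeiler-Lehman kernel metrics against independent oracles."""

from collections import Counter

import numpy as np
import pytest

from gsmdist import (
    CurrencyPolicy,
    MetabolicModel,
    Metabolite,
    Reaction,
    SyntheticSpec,
    ValidationError,
    build_model_graph,
    build_universe,
    generate_family,
    jaccard_distance,
    jaccard_matrix,
    presence_vector,
    wls_distance_matrix,
    wls_kernel,
)
from gsmdist.io import PresenceVector, ReactionUniverse
from gsmdist.metrics import ModelGraph, strip_compartment

from conftest import random_model


def _pv(bits, universe, model_id="m"):
    return PresenceVector(model_id, np.array(bits, dtype=np.uint8), universe)


UNI4 = ReactionUniverse(("R1", "R2", "R3", "R4"))


# ---------------------------------------------------------------------------
# Jaccard
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "a,b,expected",
    [
        ([1, 1, 1, 0], [0, 1, 1, 1], 0.5),  # 1 - 2/4
        ([1, 0, 1, 0], [1, 0, 1, 0], 0.0),  # identity
        ([1, 1, 0, 0], [0, 0, 1, 1], 1.0),  # disjoint supports
    ],
)
def test_jaccard_distance_arithmetic(a, b, expected):
    assert jaccard_distance(_pv(a, UNI4), _pv(b, UNI4)) == pytest.approx(expected)


def test_jaccard_empty_supports_is_zero_with_warning(caplog):
    with caplog.at_level("WARNING"):
        assert jaccard_distance(_pv([0, 0, 0, 0], UNI4), _pv([0, 0, 0, 0], UNI4)) == 0.0
    assert "empty" in caplog.text


def test_jaccard_mismatched_universes_error():
    other = ReactionUniverse(("R1", "R2"))
    with pytest.raises(ValidationError, match="universes"):
        jaccard_distance(_pv([1, 0, 1, 0], UNI4), _pv([1, 0], other))


def _nested_models():
    mets = [Metabolite("A", "c")]
    r = {i: Reaction(f"R{i}", {"A": 1.0}) for i in (1, 2, 3)}
    template = MetabolicModel("t", [r[1], r[2], r[3]], mets)
    m1 = MetabolicModel("m1", [r[1]], mets)
    m2 = MetabolicModel("m2", [r[1], r[2]], mets)
    m3 = MetabolicModel("m3", [r[1], r[2], r[3]], mets)
    return template, [m1, m2, m3]


def test_jaccard_matrix_nested_sets():
    template, models = _nested_models()
    dm = jaccard_matrix(models, build_universe(template))
    expected = np.array([[0, 0.5, 2 / 3], [0.5, 0, 1 / 3], [2 / 3, 1 / 3, 0]])
    np.testing.assert_allclose(dm.values, expected)


def test_jaccard_matrix_duplicate_model_zero(default_family):
    _, models, _, template = default_family
    uni = build_universe(template)
    dup = models[0].copy()
    dup.id = "dup"
    dm = jaccard_matrix([models[0], dup, models[1]], uni)
    assert dm.values[0, 1] == 0.0


def test_jaccard_matrix_matches_set_oracle():
    """20 random models: matrix equals naive per-pair set intersection/union."""
    rng = np.random.default_rng(21)
    models = [random_model(rng, f"m{i}") for i in range(20)]
    template = template_model_of(models)
    uni = build_universe(template)
    dm = jaccard_matrix(models, uni)
    sets = [set(m.reaction_ids) for m in models]
    for i in range(20):
        for j in range(20):
            inter = len(sets[i] & sets[j])
            union = len(sets[i] | sets[j])
            expected = 0.0 if union == 0 else 1 - inter / union
            assert dm.values[i, j] == pytest.approx(expected, abs=1e-15)


def template_model_of(models):
    from gsmdist import template_model

    return template_model(SyntheticSpec(seed=7))


def test_jaccard_triangle_inequality():
    rng = np.random.default_rng(3)
    models = [random_model(rng, f"m{i}") for i in range(12)]
    dm = jaccard_matrix(models, build_universe(template_model_of(models)))
    n = dm.n
    trips = rng.integers(0, n, size=(1000, 3))
    for i, j, k in trips:
        assert dm.values[i, j] <= dm.values[i, k] + dm.values[k, j] + 1e-12


def test_distance_matrix_permutation_equivariance(default_family):
    _, models, _, template = default_family
    uni = build_universe(template)
    sub = models[:6]
    perm = [3, 1, 5, 0, 2, 4]
    for fn in (lambda ms: jaccard_matrix(ms, uni), lambda ms: wls_distance_matrix(ms, h=2)):
        base = fn(sub)
        permuted = fn([sub[i] for i in perm])
        np.testing.assert_allclose(
            permuted.values, base.values[np.ix_(perm, perm)], atol=1e-12
        )


# ---------------------------------------------------------------------------
# model graphs
# ---------------------------------------------------------------------------


def test_chain_graph_structure(chain_model):
    g = build_model_graph(chain_model, CurrencyPolicy.none())
    assert g.n_nodes == 5 and g.n_edges == 4
    # bipartite: metabolite nodes only touch reaction nodes
    for node, neigh in g.adjacency.items():
        for u in neigh:
            assert node.split(":")[0] != u.split(":")[0]


def test_policy_removes_named_metabolite(chain_model):
    g = build_model_graph(chain_model, CurrencyPolicy(ids=("A",)))
    assert g.n_nodes == 4 and g.n_edges == 2
    assert "m:A" not in g.labels


def test_default_policy_removes_currency_metabolite():
    mets = [Metabolite("h2o_c", "c"), Metabolite("X_c", "c")]
    rxns = [
        Reaction(f"R{i}", {"h2o_c": -1.0, "X_c": 1.0}) for i in range(3)
    ]
    m = MetabolicModel("m", rxns, mets).validate()
    g = build_model_graph(m)  # default policy
    assert "m:h2o_c" not in g.labels
    assert "m:X_c" in g.labels


def test_degree_threshold_removal(chain_model):
    mets = [Metabolite("hub_c", "c"), Metabolite("X_c", "c")]
    rxns = [Reaction("R0", {"hub_c": -1.0, "X_c": 1.0})] + [
        Reaction(f"R{i}", {"hub_c": -1.0}) for i in range(1, 4)
    ]
    m = MetabolicModel("m", rxns, mets).validate()
    g = build_model_graph(m, CurrencyPolicy(ids=(), degree_threshold=3))
    assert "m:hub_c" not in g.labels and "m:X_c" in g.labels


def test_strip_compartment_variants():
    assert strip_compartment("nadh_c") == "nadh"
    assert strip_compartment("glc[e]") == "glc"
    assert strip_compartment("pep") == "pep"


# ---------------------------------------------------------------------------
# WLS kernel vs independent oracle
# ---------------------------------------------------------------------------


def wl_oracle(gA: ModelGraph, gB: ModelGraph, h: int) -> int:
    """Brute-force WL subtree kernel: labels grown as explicit nested strings."""

    def features(g: ModelGraph) -> Counter:
        lab = dict(g.labels)
        counts = Counter((0, v) for v in lab.values())
        for it in range(1, h + 1):
            lab = {
                node: repr((lab[node], tuple(sorted(lab[u] for u in g.adjacency[node]))))
                for node in g.labels
            }
            counts.update((it, v) for v in lab.values())
        return counts

    fa, fb = features(gA), features(gB)
    return sum(fa[key] * fb[key] for key in fa.keys() & fb.keys())


def random_graph(rng: np.random.Generator, n_nodes: int) -> ModelGraph:
    labels = {str(i): rng.choice(list("abcde")) for i in range(n_nodes)}
    adjacency = {str(i): [] for i in range(n_nodes)}
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < 0.3:
                adjacency[str(i)].append(str(j))
                adjacency[str(j)].append(str(i))
    for v in adjacency.values():
        v.sort()
    return ModelGraph(labels, adjacency)


def test_wls_kernel_path_example_hand_expanded():
    """Path A-B vs A-B-C, h=1: hand WL expansion gives k=3 (2 at h0, 1 at h1)."""
    g1 = ModelGraph({"1": "A", "2": "B"}, {"1": ["2"], "2": ["1"]})
    g2 = ModelGraph(
        {"1": "A", "2": "B", "3": "C"}, {"1": ["2"], "2": ["1", "3"], "3": ["2"]}
    )
    assert wls_kernel(g1, g2, 1) == 3
    assert wls_kernel(g1, g1, 1) == 4
    assert wls_kernel(g2, g2, 1) == 6


def test_wls_self_kernel_is_sum_of_squared_label_counts():
    rng = np.random.default_rng(8)
    g = random_graph(rng, 10)
    assert wls_kernel(g, g, 2) == wl_oracle(g, g, 2)


def test_wls_disjoint_labels_zero():
    g1 = ModelGraph({"1": "A"}, {"1": []})
    g2 = ModelGraph({"1": "Z"}, {"1": []})
    assert wls_kernel(g1, g2, 3) == 0


def test_wls_kernel_matches_oracle_on_random_graphs():
    rng = np.random.default_rng(17)
    graphs = [random_graph(rng, int(rng.integers(4, 12))) for _ in range(10)]
    for i in range(10):
        for j in range(i, 10):
            k = wls_kernel(graphs[i], graphs[j], 3)
            assert isinstance(k, int)
            assert k == wl_oracle(graphs[i], graphs[j], 3)


def test_wls_cauchy_schwarz():
    rng = np.random.default_rng(9)
    for _ in range(20):
        gA, gB = random_graph(rng, 8), random_graph(rng, 9)
        k_ab = wls_kernel(gA, gB, 3)
        assert k_ab**2 <= wls_kernel(gA, gA, 3) * wls_kernel(gB, gB, 3)


def test_wls_distance_matrix_identical_and_disjoint(default_family):
    _, models, _, _ = default_family
    dup = models[0].copy()
    dup.id = "dup"
    dm = wls_distance_matrix([models[0], dup, models[12]], h=3)
    assert dm.values[0, 1] == pytest.approx(0.0, abs=1e-12)
    assert 0 < dm.values[0, 2] <= 1


def test_wls_distance_matrix_matches_normalized_oracle():
    rng = np.random.default_rng(23)
    models = [random_model(rng, f"m{i}") for i in range(10)]
    dm = wls_distance_matrix(models, CurrencyPolicy.none(), h=3)
    graphs = [build_model_graph(m, CurrencyPolicy.none()) for m in models]
    for i in range(10):
        for j in range(10):
            kij = wl_oracle(graphs[i], graphs[j], 3)
            kii = wl_oracle(graphs[i], graphs[i], 3)
            kjj = wl_oracle(graphs[j], graphs[j], 3)
            expected = 0.0 if i == j else 1 - kij / np.sqrt(kii * kjj)
            assert dm.values[i, j] == pytest.approx(expected, abs=1e-12)


def test_wls_empty_graph_errors():
    m1 = MetabolicModel("empty1")
    m2 = MetabolicModel("empty2")
    with pytest.raises(ValidationError, match="empty1"):
        wls_distance_matrix([m1, m2])


def test_negative_h_rejected():
    g = ModelGraph({"1": "A"}, {"1": []})
    with pytest.raises(ValueError):
        wls_kernel(g, g, -1)
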