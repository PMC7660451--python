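"""Kernel-PCA embedding, Mantel test, and the Kruskal-Wallis screen."""

import itertools

import numpy as np
import pytest
from scipy import stats
from scipy.spatial.distance import cdist

from gsmdist import (
    DistanceMatrix,
    Labeling,
    NormalizedFluxMatrix,
    ValidationError,
    flag_outlier_fluxes,
    kernel_pca,
    kruskal_wallis_screen,
    mantel,
    pathway_counts,
    trajectories,
)
from gsmdist.analysis import ScreenResult


def _dm(values, ids=None, name="test"):
    values = np.asarray(values, float)
    ids = ids or [f"m{i}" for i in range(len(values))]
    return DistanceMatrix(list(ids), values, name)


def _euclidean_dm(points, ids=None):
    return _dm(cdist(points, points), ids)


# ---------------------------------------------------------------------------
# kernel PCA
# ---------------------------------------------------------------------------


def test_collinear_points_exact_1d_embedding():
    dm = _dm([[0, 1, 2], [1, 0, 1], [2, 1, 0]])
    emb = kernel_pca(dm, n_components=1)
    coords = emb.coordinates[:, 0]
    rec = np.abs(coords[:, None] - coords[None, :])
    np.testing.assert_allclose(rec, dm.values, atol=1e-9)


def test_zero_distances_zero_coordinates():
    emb = kernel_pca(_dm(np.zeros((4, 4))), n_components=2)
    np.testing.assert_allclose(emb.coordinates, 0.0, atol=1e-12)


def test_planar_points_reconstruction():
    rng = np.random.default_rng(19)
    pts = rng.normal(size=(20, 2))
    emb = kernel_pca(_euclidean_dm(pts), n_components=2)
    rec = cdist(emb.coordinates, emb.coordinates)
    orig = cdist(pts, pts)
    iu = np.triu_indices(20, 1)
    r = np.corrcoef(rec[iu], orig[iu])[0, 1]
    assert r >= 0.999


def test_explained_variance_shape():
    rng = np.random.default_rng(7)
    pts = rng.normal(size=(15, 4))
    emb = kernel_pca(_euclidean_dm(pts), n_components=4)
    ev = emb.explained_variance
    assert (np.diff(ev) <= 1e-12).all()  # non-increasing
    assert 0 < ev.sum() <= 1 + 1e-12
    assert (ev >= 0).all() and (ev <= 1).all()


def test_components_truncated_with_warning(caplog):
    dm = _dm([[0, 1, 2], [1, 0, 1], [2, 1, 0]])  # collinear: 1 positive eigenvalue
    with caplog.at_level("WARNING"):
        emb = kernel_pca(dm, n_components=3)
    assert emb.coordinates.shape[1] == 1
    assert "truncating" in caplog.text


def test_embedding_deterministic():
    rng = np.random.default_rng(3)
    dm = _euclidean_dm(rng.normal(size=(10, 3)))
    a = kernel_pca(dm, 2).coordinates
    b = kernel_pca(dm, 2).coordinates
    np.testing.assert_array_equal(a, b)


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------


def test_trajectories_norms():
    ids = ["a", "b", "c"]
    coords = np.array([[0.0, 0.0], [3.0, 4.0], [1.0, 1.0]])
    from gsmdist.analysis import Embedding

    emb = Embedding(ids, coords, np.array([0.6, 0.4]))
    trs = trajectories(emb, [("a", "a", "s0"), ("a", "b", "s1")])
    assert trs[0].magnitude == 0.0
    assert trs[1].magnitude == pytest.approx(5.0)
    rng = np.random.default_rng(2)
    pts = rng.normal(size=(12, 2))
    emb12 = Embedding([f"m{i}" for i in range(12)], pts, np.array([0.5, 0.5]))
    pairs = [(f"m{i}", f"m{11 - i}", f"s{i}") for i in range(6)]
    for t in trajectories(emb12, pairs):
        i, j = int(t.start_id[1:]), int(t.end_id[1:])
        assert t.magnitude == pytest.approx(np.linalg.norm(pts[j] - pts[i]))
    with pytest.raises(KeyError, match="zz"):
        trajectories(emb, [("a", "zz", "s")])


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------


def _random_dm(rng, n, ids=None):
    pts = rng.normal(size=(n, 3))
    return _euclidean_dm(pts, ids)


def test_mantel_perfect_linear_relation():
    rng = np.random.default_rng(1)
    d1 = _random_dm(rng, 8)
    d2 = _dm(2 * d1.values, d1.ids)
    res = mantel(d1, d2, n_permutations=99, seed=0)
    assert res.r == pytest.approx(1.0, abs=1e-12)


def test_mantel_self_p_is_addone_minimum():
    """d vs itself: observed r=1 beats every non-identity permutation on a
    generic matrix, so p hits the add-one lower bound."""
    rng = np.random.default_rng(5)
    d = _random_dm(rng, 8)
    res = mantel(d, d, n_permutations=199, seed=3)
    assert res.p_value == pytest.approx(1 / 200)


def test_mantel_exhaustive_small_case():
    """n=5: compare permutation p-value against full enumeration of all 120."""
    rng = np.random.default_rng(8)
    d1 = _random_dm(rng, 5)
    d2 = _random_dm(rng, 5, ids=d1.ids)
    iu = np.triu_indices(5, 1)

    def pearson(a, b):
        a, b = a[iu], b[iu]
        return np.corrcoef(a, b)[0, 1]

    r_obs = pearson(d1.values, d2.values)
    count = sum(
        1
        for perm in itertools.permutations(range(5))
        if abs(pearson(d1.values, d2.values[np.ix_(perm, perm)])) >= abs(r_obs) - 1e-15
    )
    exact_p = count / 120
    res = mantel(d1, d2, n_permutations=4999, seed=0)
    assert res.r == pytest.approx(r_obs, abs=1e-12)
    assert res.p_value == pytest.approx(exact_p, abs=0.03)


def test_mantel_symmetry_and_errors():
    rng = np.random.default_rng(9)
    d1 = _random_dm(rng, 6)
    d2 = _random_dm(rng, 6, ids=d1.ids)
    r12 = mantel(d1, d2, 99, seed=1).r
    r21 = mantel(d2, d1, 99, seed=1).r
    assert r12 == pytest.approx(r21, abs=1e-12)
    assert abs(r12) <= 1
    with pytest.raises(ValidationError):
        mantel(d1, _random_dm(rng, 6, ids=[f"x{i}" for i in range(6)]))
    with pytest.raises(ValueError, match="zero variance"):
        mantel(d1, _dm(np.ones((6, 6)) - np.eye(6), d1.ids), 99, 0)


def test_mantel_deterministic():
    rng = np.random.default_rng(11)
    d1 = _random_dm(rng, 8)
    d2 = _random_dm(rng, 8, ids=d1.ids)
    a = mantel(d1, d2, 999, seed=7)
    b = mantel(d1, d2, 999, seed=7)
    assert a == b


# ---------------------------------------------------------------------------
# Kruskal-Wallis screen
# ---------------------------------------------------------------------------


def _nfm(values, ids=None, subsystems=None):
    values = np.asarray(values, float)
    ids = ids or [f"m{i}" for i in range(values.shape[0])]
    cols = [f"r{j}" for j in range(values.shape[1])]
    return NormalizedFluxMatrix(
        ids, cols, values, [], np.zeros(values.shape, bool), subsystems or {}
    )


def _lab(arr, ids=None):
    ids = ids or [f"m{i}" for i in range(len(arr))]
    return Labeling(dict(zip(ids, arr)))


def test_kw_textbook_example():
    """Groups {1,2,3} vs {4,5,6}: H = 12/(6·7)·(6²/3+15²/3) − 3·7 = 27/7."""
    col = np.array([[1], [2], [3], [4], [5], [6]], float)
    res = kruskal_wallis_screen(_nfm(col), _lab([0, 0, 0, 1, 1, 1]))
    assert res[0].statistic == pytest.approx(27 / 7, rel=1e-9)
    assert res[0].p_value == pytest.approx(
        stats.chi2.sf(27 / 7, df=1), rel=1e-9
    )
    assert res[0].significant  # p ≈ 0.0495 < 0.05


def test_kw_tied_column_convention():
    col = np.ones((6, 1))
    res = kruskal_wallis_screen(_nfm(col), _lab([0, 0, 0, 1, 1, 1]))
    assert res[0].statistic == 0.0 and res[0].p_value == 1.0
    assert not res[0].significant


def test_kw_identical_groups_not_significant():
    col = np.array([[1], [2], [3], [1], [2], [3]], float)
    res = kruskal_wallis_screen(_nfm(col), _lab([0, 0, 0, 1, 1, 1]))
    assert res[0].statistic == pytest.approx(0.0, abs=1e-9)


def test_kw_small_group_rejected():
    with pytest.raises(ValueError, match="fewer than 2"):
        kruskal_wallis_screen(_nfm(np.ones((3, 1))), _lab([0, 0, 1]))


def test_kw_monotone_transformation_invariance():
    rng = np.random.default_rng(15)
    col = rng.normal(size=(12, 1))
    lab = _lab([0] * 6 + [1] * 6)
    h1 = kruskal_wallis_screen(_nfm(col), lab)[0].statistic
    h2 = kruskal_wallis_screen(_nfm(np.exp(3 * col)), lab)[0].statistic
    assert h1 == pytest.approx(h2, rel=1e-12)


def test_kw_results_sorted_by_p_and_carry_subsystem():
    rng = np.random.default_rng(16)
    null_col = rng.normal(size=(12, 1))
    shifted = np.vstack([rng.normal(size=(6, 1)), rng.normal(5, 1, size=(6, 1))])
    values = np.hstack([null_col, shifted])
    subs = {"r0": "Transport", "r1": "Fatty acid oxidation"}
    res = kruskal_wallis_screen(_nfm(values, subsystems=subs), _lab([0] * 6 + [1] * 6))
    assert res[0].reaction_id == "r1"  # strongly shifted column first
    assert [r.p_value for r in res] == sorted(r.p_value for r in res)
    assert res[0].subsystem == "Fatty acid oxidation"


def test_bh_correction_is_more_conservative():
    rng = np.random.default_rng(20)
    values = rng.normal(size=(12, 40))
    lab = _lab([0] * 6 + [1] * 6)
    raw = kruskal_wallis_screen(_nfm(values), lab)
    bh = kruskal_wallis_screen(_nfm(values), lab, bh_correction=True)
    assert sum(r.significant for r in bh) <= sum(r.significant for r in raw)


# ---------------------------------------------------------------------------
# pathway counts / outliers
# ---------------------------------------------------------------------------


def test_pathway_counts_aggregation():
    results = [
        ScreenResult("r1", 5, 0.01, True, "Fatty acid oxidation"),
        ScreenResult("r2", 5, 0.01, True, "Fatty acid oxidation"),
        ScreenResult("r3", 5, 0.01, True, "Fatty acid oxidation"),
        ScreenResult("r4", 5, 0.01, True, "Transport"),
        ScreenResult("r5", 0.1, 0.9, False, "Transport"),
        ScreenResult("r6", 5, 0.01, True, ""),
    ]
    counts = pathway_counts(results)
    assert counts == {"Fatty acid oxidation": 3, "Transport": 1, "unannotated": 1}
    assert pathway_counts([ScreenResult("r", 0, 1, False, "X")]) == {}


def test_flag_outlier_fluxes_thresholds():
    values = np.array([[-1.0, 0.5], [0.0, 3.0], [1.0, -0.5]])
    nfm = _nfm(values)
    assert flag_outlier_fluxes(nfm) == [("m1", "r1", 3.0)]
    assert flag_outlier_fluxes(nfm, threshold=0.0) == [
        (f"m{i}", f"r{j}", float(values[i, j]))
        for i, j in zip(*np.where(values != 0))
    ]
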