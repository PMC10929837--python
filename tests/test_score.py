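"""Bray-Curtis / PCoA ordination, group tests, disease score and set activity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra import numpy as hnp
from scipy.spatial.distance import pdist, squareform

import ucquant as uq
from ucquant.score import DissimilarityMatrix


def _expr(values, groups=None):
    values = pd.DataFrame(values, dtype=float)
    values.index = [f"g{i}" for i in range(values.shape[0])]
    values.columns = [f"s{i}" for i in range(values.shape[1])]
    ann = pd.DataFrame({"group": groups or ["x"] * values.shape[1]}, index=values.columns)
    return uq.ExpressionMatrix(values, ann)


# -- Bray-Curtis -------------------------------------------------------------

def test_bray_curtis_hand_cases():
    d = uq.bray_curtis(_expr(np.array([[1, 0], [0, 1]])))
    assert d.values[0, 1] == pytest.approx(1.0)
    d = uq.bray_curtis(_expr(np.array([[2, 1], [2, 1]])))
    assert d.values[0, 1] == pytest.approx(1 / 3)
    d = uq.bray_curtis(_expr(np.array([[3, 3], [5, 5]])))
    assert d.values[0, 1] == 0.0


def test_bray_curtis_zero_abundance_pair_defined_as_zero():
    d = uq.bray_curtis(_expr(np.array([[0, 0, 1], [0, 0, 2]])))
    assert d.values[0, 1] == 0.0


@given(hnp.arrays(np.float64, (4, 5), elements=st.floats(0, 100)))
def test_bray_curtis_bounds_and_symmetry(matrix):
    d = uq.bray_curtis(_expr(matrix.T))  # genes x samples
    assert np.allclose(d.values, d.values.T)
    assert (d.values >= -1e-12).all() and (d.values <= 1 + 1e-12).all()
    assert np.allclose(np.diag(d.values), 0.0)


def test_bray_curtis_matches_scipy_on_nonnegative_data():
    rng = np.random.default_rng(0)
    X = rng.random((8, 20))
    ours = uq.bray_curtis(_expr(X.T)).values
    ref = squareform(pdist(X, metric="braycurtis"))
    assert np.allclose(ours, ref)


# -- PCoA --------------------------------------------------------------------

def test_pcoa_recovers_euclidean_geometry():
    rng = np.random.default_rng(1)
    pts = rng.normal(size=(12, 3))
    pts -= pts.mean(axis=0)
    D = squareform(pdist(pts))
    res = uq.pcoa(DissimilarityMatrix(D, [f"s{i}" for i in range(12)]), n_axes=3)
    rec = squareform(pdist(res.coordinates.to_numpy()))
    assert np.allclose(rec, D, atol=1e-8)


def test_pcoa_two_samples_forced_geometry():
    D = np.array([[0.0, 0.6], [0.6, 0.0]])
    res = uq.pcoa(DissimilarityMatrix(D, ["a", "b"]), n_axes=1)
    assert sorted(res.coordinates["PCoA1"].tolist()) == pytest.approx([-0.3, 0.3])


def test_pcoa_regular_simplex_equal_eigenvalues():
    n = 5
    D = np.ones((n, n)) - np.eye(n)
    res = uq.pcoa(DissimilarityMatrix(D, [f"s{i}" for i in range(n)]), n_axes=n - 1)
    pos = res.eigenvalues[res.eigenvalues > 1e-10]
    assert len(pos) == n - 1
    assert np.allclose(pos, pos[0])


def test_pcoa_matches_skbio():
    skbio_ordination = pytest.importorskip("skbio.stats.ordination")
    from skbio import DistanceMatrix as SkbioDM

    rng = np.random.default_rng(2)
    X = rng.random((10, 6))
    D = squareform(pdist(X, metric="braycurtis"))
    ours = uq.pcoa(DissimilarityMatrix(D, [str(i) for i in range(10)]), n_axes=2)
    ref = skbio_ordination.pcoa(SkbioDM(D))
    for k in range(2):
        a = ours.coordinates.iloc[:, k].to_numpy()
        b = ref.samples.iloc[:, k].to_numpy()
        assert np.allclose(np.abs(a), np.abs(b), atol=1e-8)


# -- ANOSIM / PERMANOVA ------------------------------------------------------

@pytest.fixture(scope="module")
def separated():
    rng = np.random.default_rng(3)
    a = rng.normal(0, 0.1, size=(8, 4))
    b = rng.normal(5, 0.1, size=(8, 4))
    D = squareform(pdist(np.vstack([a, b])))
    labels = np.array(["a"] * 8 + ["b"] * 8)
    return DissimilarityMatrix(D, [f"s{i}" for i in range(16)]), labels


def test_anosim_perfect_separation_gives_r_one(separated):
    d, labels = separated
    r, p = uq.anosim(d, labels, n_perm=199, seed=1)
    assert r == pytest.approx(1.0)
    assert p <= 0.01


def test_anosim_matches_skbio(separated):
    skbio_distance = pytest.importorskip("skbio.stats.distance")
    from skbio import DistanceMatrix as SkbioDM

    rng = np.random.default_rng(4)
    X = rng.normal(size=(14, 5))
    X[:7] += 1.0
    D = squareform(pdist(X))
    labels = ["a"] * 7 + ["b"] * 7
    ids = [str(i) for i in range(14)]
    r, _ = uq.anosim(DissimilarityMatrix(D, ids), np.array(labels), n_perm=99, seed=0)
    ref = skbio_distance.anosim(SkbioDM(D, ids), grouping=labels, permutations=99)
    assert r == pytest.approx(ref["test statistic"], abs=1e-10)


def test_permanova_matches_skbio_statistic():
    skbio_distance = pytest.importorskip("skbio.stats.distance")
    from skbio import DistanceMatrix as SkbioDM

    rng = np.random.default_rng(5)
    X = rng.normal(size=(15, 4))
    X[:5] += 0.8
    D = squareform(pdist(X))
    labels = ["a"] * 5 + ["b"] * 10
    ids = [str(i) for i in range(15)]
    f, _ = uq.permanova(DissimilarityMatrix(D, ids), np.array(labels), n_perm=99, seed=0)
    ref = skbio_distance.permanova(SkbioDM(D, ids), grouping=labels, permutations=99)
    assert f == pytest.approx(ref["test statistic"], abs=1e-10)


def test_group_tests_reject_single_group(separated):
    d, _ = separated
    with pytest.raises(ValueError):
        uq.anosim(d, np.array(["a"] * 16))
    with pytest.raises(ValueError):
        uq.permanova(d, np.array(["a"] * 16))


def test_permutation_p_granularity():
    rng = np.random.default_rng(6)
    D = squareform(pdist(rng.normal(size=(4, 3))))
    labels = np.array(["a", "a", "b", "b"])
    _, p = uq.permanova(DissimilarityMatrix(D, list("wxyz")), labels, n_perm=99, seed=1)
    assert p >= 1 / 100
    assert round(p * 100, 6) == int(round(p * 100))


# -- UCRScore ----------------------------------------------------------------

@pytest.fixture(scope="module")
def scored_fixture():
    spec = uq.SimSpec(n_genes=300, seed=21)
    (expr, truth), = uq.simulate_cohorts(spec)
    panel = uq.SignaturePanel(
        [(g, 1) for g in truth["up_genes"]] + [(g, -1) for g in truth["down_genes"]]
    )
    sub = expr.subset_genes(panel.genes)
    res = uq.pcoa(uq.bray_curtis(sub), n_axes=2)
    return res, sub, panel


def test_score_strata_enrich_cases(scored_fixture):
    res, sub, panel = scored_fixture
    table = uq.compute_ucrscore(res, sub, panel)
    high = table[table["stratum"] == "High"]
    low = table[table["stratum"] == "Low"]
    assert (high["group"] == "case").mean() > (low["group"] == "case").mean()
    assert abs(len(high) - len(low)) <= 1


def test_score_invariant_to_axis_sign_flip(scored_fixture):
    res, sub, panel = scored_fixture
    flipped = uq.PCoAResult(-res.coordinates, res.eigenvalues, res.negative_mass)
    a = uq.compute_ucrscore(res, sub, panel)
    b = uq.compute_ucrscore(flipped, sub, panel)
    assert (a["stratum"] == b["stratum"]).all()


def test_identical_samples_cannot_stratify():
    values = np.tile([[1.0], [2.0]], (1, 6))
    expr = _expr(values)
    with pytest.raises(ValueError):
        res = uq.pcoa(uq.bray_curtis(expr), n_axes=2)
        uq.compute_ucrscore(res, expr, uq.SignaturePanel([("g0", 1)]))


def test_weighted_mode_runs(scored_fixture):
    res, sub, panel = scored_fixture
    table = uq.compute_ucrscore(res, sub, panel, mode="weighted")
    assert set(table["stratum"]) == {"High", "Low"}


# -- activity scoring --------------------------------------------------------

def test_activity_score_maximal_when_set_tops_ranking():
    values = np.array([[9.0, 8.0], [8.5, 9.5], [1.0, 1.2], [0.5, 0.1], [0.2, 0.3]])
    expr = _expr(values)
    sets = uq.GeneSetCollection({"top": ["g0", "g1"]})
    res = uq.activity_score(expr, sets, top_fraction=0.6)
    assert np.allclose(res.scores["top"], 1.0)


def test_activity_score_matches_brute_force():
    rng = np.random.default_rng(7)
    values = rng.random((40, 3))
    expr = _expr(values)
    members = ["g3", "g11", "g25", "g38"]
    res = uq.activity_score(expr, uq.GeneSetCollection({"s": members}), top_fraction=0.5)
    w = int(np.ceil(0.5 * 40))
    for c, col in enumerate(expr.values.columns):
        order = np.argsort(-values[:, c], kind="stable")[:w]
        names = [f"g{i}" for i in order]
        curve = np.cumsum([n in members for n in names])
        max_area = sum(min(k, len(members)) for k in range(1, w + 1))
        assert res.scores.loc[col, "s"] == pytest.approx(curve.sum() / max_area)


def test_activity_score_empty_overlap_is_na():
    expr = _expr(np.random.default_rng(8).random((10, 2)))
    res = uq.activity_score(expr, uq.GeneSetCollection({"alien": ["nope"]}), 0.5)
    assert res.scores["alien"].isna().all()


def test_threshold_cells_extremes_and_recovery():
    expr, truth = uq.simulate_cells(seed=9)
    panel = uq.SignaturePanel(truth["panel"])
    scores = uq.activity_score(expr, uq.GeneSetCollection({"panel": panel.genes}), 0.05)
    flags_all, n_all = uq.threshold_cells(scores, 0.0)
    assert n_all == int((scores.scores["panel"] > 0).sum())
    _, n_none = uq.threshold_cells(scores, 1.0)
    assert n_none == 0

    flags, _ = uq.threshold_cells(scores, 0.15)
    truth_set = set(truth["active_cells"])
    tp = sum(1 for c in flags.index[flags] if c in truth_set)
    prec = tp / max(1, int(flags.sum()))
    rec = tp / len(truth_set)
    f1 = 2 * prec * rec / (prec + rec)
    assert f1 >= 0.9


def test_cell_ucrscore_both_definitions_agree_on_ordering():
    expr, truth = uq.simulate_cells(seed=10)
    panel = uq.SignaturePanel(truth["panel"])
    mean_s = uq.cell_ucrscore(expr, panel, method="mean")
    auc_s = uq.cell_ucrscore(expr, panel, method="auc")
    assert np.corrcoef(mean_s, auc_s)[0, 1] > 0.7
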