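"""Differential expression, divergence statistic and module detection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra import numpy as hnp

import ucquant as uq
from conftest import jaccard


# -- differential expression -------------------------------------------------

def test_identical_groups_yield_no_calls():
    # case samples duplicate the control samples exactly
    values = pd.DataFrame(
        np.array([[5, 5, 5, 5], [2, 3, 2, 3], [1, 4, 1, 4]], dtype=float),
        index=["gA", "gB", "gC"], columns=["s1", "s2", "s3", "s4"],
    )
    ann = pd.DataFrame({"group": ["case", "case", "control", "control"]}, index=values.columns)
    expr = uq.ExpressionMatrix(values, ann)
    deg = uq.differential_expression(expr)
    assert np.allclose(deg["log2_fc"], 0.0)
    assert (deg["direction"] == "ns").all()


def test_constant_gene_called_ns():
    values = pd.DataFrame(
        [[2.0, 2.0, 2.0, 2.0], [1.0, 2.0, 5.0, 6.0]],
        index=["flat", "var"], columns=["s1", "s2", "s3", "s4"],
    )
    ann = pd.DataFrame({"group": ["case", "case", "control", "control"]}, index=values.columns)
    deg = uq.differential_expression(uq.ExpressionMatrix(values, ann))
    assert deg.loc["flat", "direction"] == "ns"
    assert not np.isfinite(deg.loc["flat", "p_value"])


def test_small_group_errors(tiny_expr):
    ann = tiny_expr.annotations.copy()
    ann["group"] = ["case", "control", "control", "control"]
    expr = uq.ExpressionMatrix(tiny_expr.values, ann)
    with pytest.raises(ValueError, match="at least 2"):
        uq.differential_expression(expr)


def test_fdr_dominates_raw_p(train_cohort):
    deg = uq.differential_expression(train_cohort[0])
    ok = deg["p_value"].notna()
    assert (deg.loc[ok, "fdr"] >= deg.loc[ok, "p_value"] - 1e-12).all()


# -- RMSD divergence ---------------------------------------------------------

def test_rmsd_hand_cases():
    assert uq.rmsd_divergence([3.1, 7.2], [3.1, 7.2]) == 0.0
    assert uq.rmsd_divergence([2, 4], [4, 8], log2_input=False) == pytest.approx(1.0)
    x = np.array([1.7, 9.3, 0.2])
    assert uq.rmsd_divergence(x, x + 1.0) == pytest.approx(1.0)  # doubling on linear scale


def test_rmsd_rejects_nonpositive_linear_values():
    with pytest.raises(ValueError, match="gB"):
        uq.rmsd_divergence([1, 2], [1, 0], gene_ids=["gA", "gB"], log2_input=False)


@given(hnp.arrays(np.float64, 5, elements=st.floats(-10, 10)),
       hnp.arrays(np.float64, 5, elements=st.floats(-10, 10)),
       hnp.arrays(np.float64, 5, elements=st.floats(-10, 10)))
def test_rmsd_is_a_pseudometric(x, y, z):
    d = uq.rmsd_divergence
    assert d(x, y) == pytest.approx(d(y, x))
    assert d(x, x) == 0.0
    assert d(x, z) <= d(x, y) + d(y, z) + 1e-9


def test_pairwise_bins_counts():
    values = pd.DataFrame(np.arange(8.0).reshape(2, 4),
                          index=["g1", "g2"], columns=list("abcd"))
    ann = pd.DataFrame({"group": ["case", "case", "control", "control"]}, index=list("abcd"))
    bins = uq.pairwise_divergence_summary(uq.ExpressionMatrix(values, ann))
    assert len(bins["between"]) == 4
    assert len(bins["within_case"]) == 1
    assert len(bins["within_control"]) == 1


def test_planted_effect_orders_divergence_bins(train_cohort):
    bins = uq.pairwise_divergence_summary(train_cohort[0])
    assert bins["between"].mean() > bins["within_control"].mean()


# -- TOM and modules ---------------------------------------------------------

def test_tom_toy_hand_value():
    a = np.full((3, 3), 0.5)
    np.fill_diagonal(a, 0.0)
    tom = uq.topological_overlap(a)
    assert tom[0, 1] == pytest.approx((0.25 + 0.5) / (1 + 1 - 0.5))


def test_tom_properties_on_random_adjacency():
    rng = np.random.default_rng(0)
    r = rng.random((30, 30))
    a = np.abs((r + r.T) / 2) ** 6
    np.fill_diagonal(a, 0.0)
    tom = uq.topological_overlap(a)
    off = ~np.eye(30, dtype=bool)
    assert np.allclose(tom, tom.T)
    assert (tom[off] >= 0).all() and (tom[off] <= 1 + 1e-12).all()


@pytest.fixture(scope="module")
def block_cohort():
    spec = uq.SimSpec(n_genes=500, n_up=0, n_down=0,
                      module_spec=[(60, 0.8), (60, 0.8)], seed=2)
    return uq.simulate_cohorts(spec)[0]


def test_planted_blocks_recovered(block_cohort):
    expr, truth = block_cohort
    mods = uq.detect_modules(expr, beta=14, min_module_size=30, top_n_variable=500)
    assert len(mods.modules) == 2
    for block in truth["blocks"]:
        best = max(mods.modules, key=lambda m: len(set(mods.module_genes(m)) & set(block)))
        assert jaccard(mods.module_genes(best), block) >= 0.9


def test_module_detection_gene_order_invariant(block_cohort):
    expr, _ = block_cohort
    rng = np.random.default_rng(1)
    perm = rng.permutation(expr.gene_ids)
    shuffled = uq.ExpressionMatrix(expr.values.loc[perm], expr.annotations)
    a = uq.detect_modules(expr, beta=14, min_module_size=30, top_n_variable=500)
    b = uq.detect_modules(shuffled, beta=14, min_module_size=30, top_n_variable=500)
    parts_a = {frozenset(a.module_genes(m)) for m in a.modules}
    parts_b = {frozenset(b.module_genes(m)) for m in b.modules}
    assert parts_a == parts_b


def test_pure_noise_has_no_trait_module():
    spec = uq.SimSpec(n_genes=300, n_up=0, n_down=0, effect_lfc=0.0, seed=6)
    (expr, _), = uq.simulate_cohorts(spec)
    mods = uq.detect_modules(expr, beta=14, min_module_size=20,
                             top_n_variable=300, cut_height=0.9999)
    if not mods.trait_correlation.empty:
        assert (mods.trait_correlation["p"] >= 0.01).all()


def test_eigengenes_have_unit_variance(block_cohort):
    expr, _ = block_cohort
    mods = uq.detect_modules(expr, beta=14, min_module_size=30, top_n_variable=500)
    assert np.allclose(mods.eigengenes.std(ddof=1), 1.0)


# -- common DEGs -------------------------------------------------------------

def test_common_degs_recovers_planted_panel():
    spec = uq.SimSpec(n_genes=400, n_up=20, n_down=20,
                      module_spec=[(60, 0.8)], plant_in_blocks=True, seed=3)
    (expr, truth), = uq.simulate_cohorts(spec)
    deg = uq.differential_expression(expr)
    mods = uq.detect_modules(expr, beta=14, min_module_size=30, top_n_variable=400)
    panel = uq.common_degs(deg, mods)
    planted = set(truth["up_genes"]) | set(truth["down_genes"])
    assert set(panel.genes) == planted
    for g, d in panel.entries:
        assert np.sign(deg.loc[g, "log2_fc"]) == d


def test_common_degs_empty_intersection_errors(train_cohort):
    expr, _ = train_cohort
    deg = uq.differential_expression(expr)
    deg["direction"] = "ns"
    mods = uq.detect_modules(expr, beta=14, min_module_size=20, top_n_variable=300)
    if mods.modules:
        with pytest.raises(ValueError, match="threshold"):
            uq.common_degs(deg, mods, key_module=mods.modules[0])
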