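"""Dual-pathway association: deviant split, chi-square, regression,
permutation thresholds, candidate intersection, expression ranking."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import emslink as el
from emslink.association import _chi2_from_counts, _ols_stats
from emslink.burden import GeneBurdenMatrix


def pheno_frame(values, line_ids=None, wt=None):
    if line_ids is None:
        line_ids = [f"L{i:03d}" for i in range(len(values))]
    return pd.DataFrame({
        "line_id": line_ids,
        "trait": values,
        "is_wt": wt if wt is not None else [False] * len(values),
    })


def burden_from_binary(B, genes=None, lines=None):
    genes = genes or [f"G{i:03d}" for i in range(B.shape[0])]
    lines = lines or [f"L{i:03d}" for i in range(B.shape[1])]
    counts = pd.DataFrame(B, index=pd.Index(genes, name="gene_id"),
                          columns=pd.Index(lines, name="line_id"))
    return GeneBurdenMatrix(counts=counts, weighted=counts.astype(float),
                            binary=(counts > 0).astype(np.int8))


# --- deviant split ---------------------------------------------------------


def test_constant_trait_gives_empty_deviant_set():
    with pytest.warns(UserWarning):
        split = el.deviant_lines(pheno_frame([5.0] * 10), "trait")
    assert len(split.deviant) == 0
    assert len(split.non_deviant) == 10


def test_zero_threshold_marks_every_line_deviant():
    split = el.deviant_lines(pheno_frame([1.0, 2.0, 3.0]), "trait", z_threshold=0.0)
    assert len(split.deviant) == 3


def test_single_outlier_detected():
    split = el.deviant_lines(pheno_frame([0.0, 0.0, 0.0, 10.0]), "trait",
                             z_threshold=1.0)
    assert list(split.deviant) == ["L003"]


def test_wild_type_center_mode():
    ph = pheno_frame([0.0, 4.0, 2.0, 2.0], wt=[False, False, True, True])
    split = el.deviant_lines(ph, "trait", center_mode="wild_type", z_threshold=0.5)
    assert split.center == 2.0
    assert set(split.deviant) == {"L000", "L001"}
    assert not set(split.lines) & {"L002", "L003"}


def test_split_partitions_population():
    rng = np.random.default_rng(0)
    ph = pheno_frame(rng.normal(size=40))
    split = el.deviant_lines(ph, "trait")
    assert len(split.deviant.intersection(split.non_deviant)) == 0
    assert len(split.deviant) + len(split.non_deviant) == 40


# --- enrichment chi-square -------------------------------------------------


def test_literal_chi2_zero_when_obs_equals_exp():
    # 4 lines, 2 deviant (L000, L002); gene carried by one deviant and one
    # non-deviant line, so Obs = 1 = Exp = 2 * 2 / 4
    B = np.array([[1, 1, 0, 0]])
    mat = burden_from_binary(B)
    ph = pheno_frame([10.0, 0.0, -10.0, 0.0])
    split = el.deviant_lines(ph, "trait", z_threshold=1.0)
    out = el.enrichment_chi2(mat, split, mode="literal")
    assert out["obs"].iloc[0] == out["exp"].iloc[0]
    assert out["chi2"].iloc[0] == pytest.approx(0.0)


def test_literal_chi2_direct_evaluation():
    # Obs=10, Exp=5 -> (10-5)^2/5 = 5
    stat, valid = _chi2_from_counts(np.array([10]), np.array([10]),
                                    n_dev=50, n_lines=100, mode="literal")
    assert valid[0]
    assert stat[0] == pytest.approx(5.0)


def test_contingency_chi2_matches_scipy_oracle(rng):
    for _ in range(100):
        n = int(rng.integers(20, 60))
        carriers = rng.integers(0, 2, size=(1, n))
        dev = rng.integers(0, 2, size=n).astype(bool)
        a = int((carriers[0][dev] == 1).sum())
        b = int((carriers[0] == 1).sum()) - a
        c = int(dev.sum()) - a
        d = n - a - b - c
        table = np.array([[a, b], [c, d]])
        stat, valid = _chi2_from_counts(np.array([a]), np.array([a + b]),
                                        n_dev=a + c, n_lines=n, mode="contingency")
        if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
            assert not valid[0]
            continue
        expected = stats.chi2_contingency(table, correction=False)
        assert stat[0] == pytest.approx(expected.statistic, abs=1e-10)


def test_chi2_zero_expectation_skipped():
    B = np.zeros((1, 10), dtype=int)
    mat = burden_from_binary(B)
    ph = pheno_frame(list(range(10)))
    split = el.deviant_lines(ph, "trait", z_threshold=1.0)
    out = el.enrichment_chi2(mat, split, mode="literal")
    assert out["skipped"].iloc[0]
    assert np.isnan(out["chi2"].iloc[0])


# --- burden regression -----------------------------------------------------


def test_perfect_linear_fit_recovers_slope():
    x = np.arange(10, dtype=float)
    B = x.reshape(1, -1)
    mat = burden_from_binary(B.astype(int))
    ph = pheno_frame(2.0 * x)
    out = el.burden_regression(mat, ph, "trait", predictor="count")
    assert out["slope"].iloc[0] == pytest.approx(2.0, abs=1e-10)
    assert out["p_reg"].iloc[0] == 0.0


def test_constant_predictor_skipped():
    mat = burden_from_binary(np.ones((1, 10), dtype=int))
    ph = pheno_frame(np.arange(10.0))
    out = el.burden_regression(mat, ph, "trait")
    assert out["skipped"].iloc[0]


def test_ols_matches_statsmodels_oracle(rng):
    import statsmodels.api as sm

    for _ in range(100):
        n = int(rng.integers(8, 30))
        x = rng.normal(size=n)
        y = rng.normal(size=n) + 0.5 * x
        slope, se, t, p, valid = _ols_stats(x.reshape(1, -1), y)
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        assert slope[0] == pytest.approx(fit.params[1], abs=1e-10)
        assert se[0] == pytest.approx(fit.bse[1], abs=1e-10)
        assert p[0] == pytest.approx(fit.pvalues[1], abs=1e-10)


def test_regression_affine_trait_invariance(rng):
    B = rng.integers(0, 3, size=(5, 30))
    mat = burden_from_binary(B)
    y = rng.normal(size=30)
    a = el.burden_regression(mat, pheno_frame(y), "trait", predictor="count")
    b = el.burden_regression(mat, pheno_frame(3.0 * y + 7.0), "trait",
                             predictor="count")
    np.testing.assert_allclose(a["t"], b["t"], atol=1e-10)
    np.testing.assert_allclose(a["p_reg"], b["p_reg"], atol=1e-12)


# --- permutation threshold -------------------------------------------------


def small_population(rng, n_genes=40, n_lines=60, freq=0.15):
    B = (rng.random((n_genes, n_lines)) < freq).astype(int)
    return burden_from_binary(B)


def test_threshold_deterministic_under_seed(rng):
    mat = small_population(rng)
    ph = pheno_frame(rng.normal(size=60))
    a = el.permutation_threshold(mat, ph, "trait", n_perm=50, seed=3)
    b = el.permutation_threshold(mat, ph, "trait", n_perm=50, seed=3)
    assert a.threshold == b.threshold
    np.testing.assert_array_equal(a.maxima, b.maxima)


def test_constant_phenotype_never_exceeds_threshold(rng):
    mat = small_population(rng)
    ph = pheno_frame([1.0] * 60)
    with pytest.warns(UserWarning):
        thr = el.permutation_threshold(mat, ph, "trait", n_perm=30, seed=1)
    reg = el.burden_regression(mat, ph, "trait")
    assert not (reg["t"].abs() > thr.threshold).any()


def test_low_n_perm_warns(rng):
    mat = small_population(rng)
    ph = pheno_frame(rng.normal(size=60))
    with pytest.warns(UserWarning):
        el.permutation_threshold(mat, ph, "trait", n_perm=10, alpha=0.05, seed=1)


def test_chi2_pathway_threshold_runs(rng):
    mat = small_population(rng)
    ph = pheno_frame(rng.normal(size=60))
    thr = el.permutation_threshold(mat, ph, "trait", pathway="chi2",
                                   n_perm=50, seed=2)
    assert thr.threshold >= 0


# --- candidate intersection ------------------------------------------------


def fake_result(p_chi2, p_reg, chi2=None, t=None):
    genes = [f"G{i:03d}" for i in range(len(p_chi2))]
    table = pd.DataFrame({
        "obs": 1, "exp": 1.0, "n_carriers": 5,
        "chi2": chi2 if chi2 is not None else 1.0 / np.asarray(p_chi2),
        "p_chi2": p_chi2,
        "slope": 1.0, "se": 1.0,
        "t": t if t is not None else 1.0 / np.asarray(p_reg),
        "p_reg": p_reg, "n": 50,
    }, index=pd.Index(genes, name="gene_id"))
    return el.AssociationResult(trait="trait", table=table)


def test_disjoint_top_lists_give_no_candidates():
    res = fake_result(p_chi2=[0.01, 0.02, 0.9, 0.8],
                      p_reg=[0.9, 0.8, 0.01, 0.02])
    cand = el.intersect_candidates(res, k=2)
    assert cand == []


def test_identical_rankings_give_min_k_candidates():
    p = [0.001, 0.002, 0.003, 0.004]
    with pytest.warns(UserWarning):
        cand = el.intersect_candidates(fake_result(p, p), k=10)
    assert len(cand) == 4


def test_intersection_matches_brute_force(rng):
    n = 50
    p1 = rng.random(n)
    p2 = rng.random(n)
    res = fake_result(p1, p2)
    k = 15
    cand = el.intersect_candidates(res, k=k)
    genes = np.array(res.table.index)
    top1 = set(genes[np.lexsort((genes, p1))][:k])
    top2 = set(genes[np.lexsort((genes, p2))][:k])
    assert set(cand) == top1 & top2


def test_threshold_filter_applied_to_candidates():
    res = fake_result(p_chi2=[0.001, 0.002], p_reg=[0.001, 0.002],
                      chi2=np.array([20.0, 3.0]), t=np.array([8.0, 1.0]))
    res.chi2_threshold = el.association.PermutationThreshold(
        threshold=10.0, pathway="chi2", n_perm=100, alpha=0.05,
        maxima=np.zeros(100), seed=0)
    res.reg_threshold = el.association.PermutationThreshold(
        threshold=4.0, pathway="regression", n_perm=100, alpha=0.05,
        maxima=np.zeros(100), seed=0)
    cand = el.intersect_candidates(res, k=2)
    assert cand == ["G000"]


# --- expression prioritization ---------------------------------------------


def expression_matrix():
    return pd.DataFrame(
        {"leaf": [0.0, 5.0, 2.0], "seed": [0.0, 1.0, 9.0]},
        index=pd.Index(["G000", "G001", "G002"], name="gene_id"),
    )


def test_silent_candidate_dropped():
    out = el.prioritize_by_expression(["G000"], expression_matrix(),
                                      ["leaf", "seed"], min_fpkm=1.0)
    assert out.empty


def test_empty_candidates_give_empty_result():
    out = el.prioritize_by_expression([], expression_matrix(), ["leaf"])
    assert out.empty


def test_unknown_tissue_rejected():
    with pytest.raises(KeyError):
        el.prioritize_by_expression(["G001"], expression_matrix(), ["root"])


def test_missing_gene_retained_with_flag():
    out = el.prioritize_by_expression(["G001", "GX"], expression_matrix(),
                                      ["leaf"])
    assert list(out["gene_id"]) == ["G001", "GX"]
    assert list(out["missing_expression"]) == [False, True]


def test_ranking_matches_brute_force(rng):
    genes = [f"G{i:03d}" for i in range(20)]
    expr = pd.DataFrame(rng.random((20, 3)) * 10,
                        index=pd.Index(genes, name="gene_id"),
                        columns=["a", "b", "c"])
    out = el.prioritize_by_expression(genes, expr, ["a", "c"], min_fpkm=2.0)
    expected = sorted(
        [(g, expr.loc[g, ["a", "c"]].max()) for g in genes
         if expr.loc[g, ["a", "c"]].max() >= 2.0],
        key=lambda x: (-x[1], x[0]),
    )
    assert list(out["gene_id"]) == [g for g, _ in expected]


# --- end-to-end null behaviour ---------------------------------------------


def test_null_pvalues_uniform_small_scale(rng):
    mat = small_population(rng, n_genes=200, n_lines=100, freq=0.2)
    ph = pheno_frame(rng.normal(size=100))
    reg = el.burden_regression(mat, ph, "trait", predictor="binary")
    ks = stats.kstest(reg["p_reg"].dropna(), "uniform")
    assert ks.pvalue > 0.01
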