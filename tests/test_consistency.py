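import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pgxagree import (AgreementResult, PgxError, ThresholdConfig,
                      calls_consistency, classify_agreement, cohen_kappa,
                      compare_datatype_consistency, call_fixed,
                      per_entity_consistency, pearson, wilcoxon_rank_sum)
from pgxagree.consistency import UNION_NOTE, summarize


# ---------------------------------------------------------------- pearson

def test_pearson_identity_and_antisymmetry():
    x = [1.0, 2.0, 5.0, 3.0]
    assert pearson(x, x, min_pairs=3) == pytest.approx(1.0)
    assert pearson(x, [-v for v in x], min_pairs=3) == pytest.approx(-1.0)


def test_pearson_matches_hand_formula():
    x, y = np.array([1.0, 2, 3]), np.array([2.0, 4, 7])
    # explicit product-moment evaluation
    num = np.sum((x - x.mean()) * (y - y.mean()))
    den = math.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
    assert pearson(x, y, min_pairs=3) == pytest.approx(num / den)


def test_pearson_undefined_cases():
    assert math.isnan(pearson([1, 2, 3], [4, 5, 6], min_pairs=10))
    assert math.isnan(pearson([1, 1, 1, 1], [1, 2, 3, 4], min_pairs=3))
    x = [1.0, 2.0, np.nan, 4.0]
    y = [1.0, np.nan, 3.0, 4.0]
    assert math.isnan(pearson(x, y, min_pairs=3))  # only 2 complete pairs
    with pytest.raises(ValueError):
        pearson([1, 2], [1, 2, 3], min_pairs=2)


@settings(derandomize=True, max_examples=40)
@given(st.integers(1, 50), st.integers(1, 10 ** 6))
def test_pearson_affine_invariance(seed, scale_ppm):
    rng = np.random.default_rng(seed)
    x, y = rng.standard_normal(20), rng.standard_normal(20)
    a = scale_ppm / 10 ** 5  # positive slope
    assert pearson(a * x + 3.0, y, min_pairs=5) == pytest.approx(
        pearson(x, y, min_pairs=5), abs=1e-9)


# ------------------------------------------------------------------ kappa

def _expand(n11, n10, n01, n00):
    a = [1] * n11 + [1] * n10 + [0] * n01 + [0] * n00
    b = [1] * n11 + [0] * n10 + [1] * n01 + [0] * n00
    return np.array(a, float), np.array(b, float)


def test_kappa_balanced_table_is_point_six():
    a, b = _expand(40, 10, 10, 40)
    # p_o = 0.8, p_e = 0.5 -> kappa = 0.6 by the definition
    assert cohen_kappa(a, b) == pytest.approx(0.6)


def test_kappa_perfect_agreement():
    a = np.array([0, 1, 1, 0, 1] * 3, float)
    assert cohen_kappa(a, a, min_pairs=5) == pytest.approx(1.0)


def test_kappa_degenerate_marginals_undefined():
    a = np.ones(20)
    assert math.isnan(cohen_kappa(a, a.copy()))


def test_kappa_rejects_non_binary():
    with pytest.raises(ValueError):
        cohen_kappa([0, 1, 2], [0, 1, 1], min_pairs=1)


def test_kappa_matches_sklearn(rng):
    sklearn = pytest.importorskip("sklearn.metrics")
    for _ in range(20):
        a = (rng.random(50) < 0.4).astype(float)
        b = (rng.random(50) < 0.6).astype(float)
        ours = cohen_kappa(a, b)
        theirs = sklearn.cohen_kappa_score(a, b)
        if math.isnan(ours):
            continue
        assert ours == pytest.approx(theirs, abs=1e-12)


@pytest.mark.parametrize("prev", [0.2, 0.5, 0.8])
def test_kappa_near_zero_for_independent_raters(prev):
    rng = np.random.default_rng(int(prev * 100))
    a = (rng.random(10_000) < prev).astype(float)
    b = (rng.random(10_000) < prev).astype(float)
    assert abs(cohen_kappa(a, b)) < 0.05


def test_kappa_invariant_to_simultaneous_label_swap(rng):
    a = (rng.random(100) < 0.3).astype(float)
    b = (rng.random(100) < 0.3).astype(float)
    assert cohen_kappa(1 - a, 1 - b) == pytest.approx(cohen_kappa(a, b))


# --------------------------------------------------------- classification

@pytest.mark.parametrize("rho,expected", [
    (0.57, "REASONABLE"),
    (0.8, "GOOD"),        # boundary inclusive
    (0.5, "BELOW"),       # reasonable is strictly above 0.5
    (0.95, "GOOD"),
    (-0.2, "BELOW"),
])
def test_rho_categories(rho, expected):
    r = classify_agreement(AgreementResult("d", 50, rho=rho))
    assert r.rho_category == expected


@pytest.mark.parametrize("kappa,expected", [
    (0.1, "POOR"), (0.25, "FAIR"), (0.4, "MODERATE"), (0.45, "MODERATE"),
    (0.6, "SUBSTANTIAL"), (0.8, "ALMOST_PERFECT"),
])
def test_kappa_landis_koch_bands(kappa, expected):
    r = classify_agreement(AgreementResult("d", 50, kappa=kappa))
    assert r.kappa_category == expected


def test_summary_fraction_in_paper_reporting_style():
    # 15 drugs of which 8 exceed the reasonable-consistency bar
    rhos = [0.9] * 3 + [0.6] * 5 + [0.3] * 7
    results = [classify_agreement(AgreementResult(f"d{i}", 30, rho=r))
               for i, r in enumerate(rhos)]
    s = summarize(results)
    assert s["fraction_rho_gt_0.5"] == pytest.approx(8 / 15)
    assert s["fraction_rho_ge_0.8"] == pytest.approx(3 / 15)
    assert s["n_rho_defined"] == 15


def test_union_fraction_is_monotone_and_labelled(rng):
    # joint reports (both statistics defined per entity) are the setting in
    # which a union of tests is quoted; there the union fraction dominates
    # each single-test fraction by construction
    for _ in range(20):
        results = [AgreementResult(f"e{i}", 30, rho=rng.uniform(-1, 1),
                                   kappa=rng.uniform(-1, 1))
                   for i in range(int(rng.integers(3, 15)))]
        s = summarize(results)
        union = s["fraction_pass_union"]
        assert union >= s["fraction_rho_gt_0.5"] - 1e-12
        assert union >= s["fraction_kappa_ge_0.4"] - 1e-12
        assert s["union_note"] == UNION_NOTE


def test_merge_reports_joins_statistics_per_entity():
    from pgxagree.consistency import merge_reports, ConsistencyReport
    rho_rep = ConsistencyReport(("A", "B"), "AUC", [
        classify_agreement(AgreementResult("d1", 30, rho=0.9)),
        classify_agreement(AgreementResult("d2", 30, rho=0.2)),
    ])
    kap_rep = ConsistencyReport(("A", "B"), "CALLS_AUC_WATERFALL", [
        classify_agreement(AgreementResult("d1", 30, kappa=0.1)),
        classify_agreement(AgreementResult("d2", 30, kappa=0.7)),
    ])
    merged = merge_reports(rho_rep, kap_rep)
    by = {r.entity_id: r for r in merged.results}
    assert by["d1"].rho == 0.9 and by["d1"].kappa == 0.1
    # d1 passes by rho only, d2 by kappa only -> union covers both
    assert merged.summary["fraction_pass_union"] == 1.0
    assert merged.summary["fraction_rho_gt_0.5"] == 0.5
    assert merged.summary["fraction_kappa_ge_0.4"] == 0.5


# -------------------------------------------------------------- reports

def test_identical_matrices_give_perfect_consistency(aligned_pair):
    p = aligned_pair
    p.study_b.sensitivity["AUC"] = p.study_a.sensitivity["AUC"]
    rep = per_entity_consistency(p, "AUC", min_pairs=5)
    assert all(r.rho == pytest.approx(1.0) for r in rep.results)
    assert rep.summary["fraction_rho_ge_0.8"] == 1.0


def test_mutation_report_uses_kappa(aligned_pair):
    rep = per_entity_consistency(aligned_pair, "MUTATION", min_pairs=5)
    assert rep.summary["n_kappa_defined"] > 0
    assert rep.summary["n_rho_defined"] == 0


def test_missing_datatype_errors(aligned_pair):
    del aligned_pair.study_b.profiles["CNV"]
    with pytest.raises(PgxError):
        per_entity_consistency(aligned_pair, "CNV")


def test_calls_consistency_alignment_required(aligned_pair):
    ca = call_fixed(aligned_pair.study_a.sensitivity["AUC"])
    cb = call_fixed(aligned_pair.study_b.sensitivity["AUC"])
    rep = calls_consistency(ca, cb, min_pairs=5)
    assert rep.datatype == "CALLS_AUC_FIXED"
    assert len(rep.results) == len(ca.drugs)
    cb.calls = cb.calls.iloc[::-1]
    with pytest.raises(PgxError):
        calls_consistency(ca, cb)


# -------------------------------------------------------------- wilcoxon

def rank_sum_enumeration(x, y, alternative):
    """Independent oracle: enumerate all rank assignments (no ties)."""
    m, n = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = pooled.argsort().argsort() + 1
    w_obs = ranks[:m].sum()
    sums = np.array([sum(c) for c in
                     itertools.combinations(range(1, m + n + 1), m)])
    p_less = np.mean(sums <= w_obs)
    p_greater = np.mean(sums >= w_obs)
    if alternative == "less":
        return p_less
    if alternative == "greater":
        return p_greater
    return min(1.0, 2 * min(p_less, p_greater))


def test_wilcoxon_small_sample_exact():
    res = wilcoxon_rank_sum([1, 2], [3, 4], alternative="less")
    assert res["method"] == "exact"
    assert res["p"] == pytest.approx(1 / 6)
    assert res["statistic"] == 3.0  # ranks 1 + 2


def test_wilcoxon_identical_multisets_two_sided():
    x = [1.0, 2.0, 3.0, 4.0]
    res = wilcoxon_rank_sum(x, list(x), alternative="two_sided")
    assert res["p"] >= 0.99


def test_wilcoxon_exact_matches_enumeration(rng):
    for _ in range(10):
        pool = rng.permutation(np.arange(16.0))
        x, y = pool[:8], pool[8:]
        for alt in ("less", "greater", "two_sided"):
            res = wilcoxon_rank_sum(x, y, alternative=alt)
            assert res["method"] == "exact"
            assert res["p"] == pytest.approx(
                rank_sum_enumeration(x, y, alt), abs=1e-12)


def test_wilcoxon_exact_and_normal_agree(rng):
    for _ in range(10):
        x = rng.standard_normal(8)
        y = rng.standard_normal(8) + 0.5
        exact = wilcoxon_rank_sum(x, y, "less", method="exact")["p"]
        approx = wilcoxon_rank_sum(x, y, "less", method="asymptotic")["p"]
        assert abs(exact - approx) < 0.05


def test_wilcoxon_empty_vector_errors():
    with pytest.raises(ValueError):
        wilcoxon_rank_sum([], [1.0], "less")


def test_compare_datatype_consistency_separated_distributions():
    mk = lambda rhos, name: type("R", (), {
        "defined_rho": lambda self=None, v=tuple(rhos): np.array(v),
        "defined_kappa": lambda self=None: np.array([]),
        "datatype": name})()
    genomic = mk([0.9, 0.88, 0.92, 0.91, 0.89], "CNV")
    pharm = mk([0.3, 0.28, 0.35, 0.31, 0.29], "AUC")
    out = compare_datatype_consistency(genomic, pharm, "greater")
    assert out["p"] < 0.05
    same = compare_datatype_consistency(genomic, genomic, "greater")
    assert same["p"] >= 0.5
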