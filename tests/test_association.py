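import itertools
import math

import numpy as np
import pandas as pd
import pytest

from pgxagree import (DesignSpec, PgxError, associate, biomarker_concordance,
                      design, run_association_screen, run_design_comparison,
                      SimulationParams, generate_pair)
from pgxagree.association import _bh_adjust, _grid_ttest


def permutation_p(response, mutation):
    """Exact two-sided permutation p over all mutant/wild-type splits."""
    r = np.asarray(response, float)
    n_mut = int(np.sum(mutation))
    idx = range(len(r))

    def tstat(mut_idx):
        mut = r[list(mut_idx)]
        wt = np.delete(r, list(mut_idx))
        sp2 = ((np.sum((mut - mut.mean()) ** 2) + np.sum((wt - wt.mean()) ** 2))
               / (len(r) - 2))
        if sp2 == 0:
            return math.inf if mut.mean() != wt.mean() else 0.0
        return (mut.mean() - wt.mean()) / math.sqrt(
            sp2 * (1 / len(mut) + 1 / len(wt)))

    obs = abs(tstat(np.flatnonzero(np.asarray(mutation) == 1)))
    stats = [abs(tstat(c)) for c in itertools.combinations(idx, n_mut)]
    return np.mean([s >= obs - 1e-12 for s in stats])


def test_associate_no_effect():
    r = np.array([1.0, 2, 3, 1, 2, 3])
    m = np.array([0.0, 0, 0, 1, 1, 1])
    res = associate(r, m)
    assert res.effect == pytest.approx(0.0)
    assert res.p == pytest.approx(1.0)


def test_associate_effect_and_permutation_granularity():
    r = np.array([1.0, 2, 3, 7, 8, 9])
    m = np.array([0.0, 0, 0, 1, 1, 1])
    res = associate(r, m)
    assert res.effect == pytest.approx(6.0)
    assert res.n_mut == res.n_wt == 3
    # exact permutation p over all C(6,3)=20 splits is 2/20; the t-based p
    # must agree within the oracle's granularity
    p_perm = permutation_p(r, m)
    assert p_perm == pytest.approx(0.1)
    assert abs(res.p - p_perm) < 0.12


def test_associate_matches_permutation_on_random_small_inputs(rng):
    for _ in range(15):
        n = int(rng.integers(8, 11))
        r = rng.standard_normal(n)
        m = np.zeros(n)
        m[: int(rng.integers(3, n - 2))] = 1.0
        rng.shuffle(m)
        res = associate(r, m)
        assert abs(res.p - permutation_p(r, m)) < 0.12


def test_associate_degenerate_group_flagged():
    res = associate(np.arange(6.0), np.ones(6))
    assert not res.defined
    assert math.isnan(res.p)


def test_associate_matches_scipy_ttest(rng):
    from scipy import stats
    r = rng.standard_normal(30)
    m = (rng.random(30) < 0.4).astype(float)
    res = associate(r, m)
    t, p = stats.ttest_ind(r[m == 1], r[m == 0], equal_var=True)
    assert res.statistic == pytest.approx(float(t))
    assert res.p == pytest.approx(float(p))


def test_grid_ttest_equals_scalar_associate(rng):
    genes = [f"G{i}" for i in range(6)]
    cells = [f"C{i}" for i in range(40)]
    drugs = [f"D{i}" for i in range(4)]
    mut = pd.DataFrame((rng.random((6, 40)) < 0.3).astype(float),
                       index=genes, columns=cells)
    mut.iloc[0, :3] = np.nan
    resp = pd.DataFrame(rng.standard_normal((40, 4)), index=cells,
                        columns=drugs)
    resp.iloc[5:9, 1] = np.nan
    grid = _grid_ttest(mut, resp, min_group=3).set_index(["gene", "drug"])
    for g in genes:
        for d in drugs:
            ref = associate(resp[d].to_numpy(), mut.loc[g, cells].to_numpy(),
                            min_group=3)
            row = grid.loc[(g, d)]
            assert row["n_mut"] == ref.n_mut and row["n_wt"] == ref.n_wt
            if ref.defined:
                assert row["effect"] == pytest.approx(ref.effect)
                assert row["p"] == pytest.approx(ref.p)
            else:
                assert not row["defined"]


def test_bh_q_values_monotone_in_p_rank(rng):
    df = pd.DataFrame({"p": rng.random(50), "defined": True})
    out = _bh_adjust(df).sort_values("p")
    q = out["q"].to_numpy()
    assert (np.diff(q) >= -1e-12).all()
    assert (q <= 1.0 + 1e-12).all()
    assert (q >= out["p"].to_numpy() - 1e-12).all()


def test_design_spec_validation():
    with pytest.raises(ValueError):
        DesignSpec("A_INDEPENDENT", genomic_source="study_a")
    with pytest.raises(ValueError):
        DesignSpec("B_SHARED_MUTATIONS", genomic_source="own")
    with pytest.raises(ValueError):
        DesignSpec("C_SHARED_GENOMICS_MIXED_MEASURES",
                   genomic_source="study_a", measure_a="AUC", measure_b="AUC")
    c = design("c")
    assert {c.measure_a, c.measure_b} == {"AUC", "IC50"}


def test_screen_provenance_is_auditable(aligned_pair):
    la, lb = run_association_screen(aligned_pair, design("b"))
    assert la["mutation_source"].unique().tolist() == ["STUDY_A"]
    assert lb["mutation_source"].unique().tolist() == ["STUDY_A"]
    lc_a, lc_b = run_association_screen(aligned_pair, design("c"))
    assert lc_a["measure"].unique().tolist() == ["AUC"]
    assert lc_b["measure"].unique().tolist() == ["IC50"]
    ld_a, ld_b = run_association_screen(aligned_pair, design("a"))
    assert ld_a["mutation_source"].unique().tolist() == ["STUDY_A"]
    assert ld_b["mutation_source"].unique().tolist() == ["STUDY_B"]


def test_design_a_on_identical_studies_gives_identical_lists(aligned_pair):
    p = aligned_pair
    p.study_b.sensitivity["AUC"] = p.study_a.sensitivity["AUC"]
    p.study_b.profiles["MUTATION"] = p.study_a.profiles["MUTATION"]
    la, lb = run_association_screen(p, design("a"))
    pd.testing.assert_frame_equal(
        la.drop(columns="mutation_source"), lb.drop(columns="mutation_source"))


def test_concordance_identical_and_independent(rng):
    genes = [f"G{i}" for i in range(10)]
    base = pd.DataFrame({
        "gene": genes, "drug": "D1",
        "effect": rng.standard_normal(10),
        "statistic": 0.0,
        "p": [1e-8] * 3 + list(0.5 + 0.4 * rng.random(7)),
        "n_mut": 10, "n_wt": 10, "defined": True,
    })
    base = _bh_adjust(base)
    same = biomarker_concordance(base, base.copy(), sig_q=0.05)
    assert same["effect_rho"] == pytest.approx(1.0)
    assert same["hit_kappa"] == pytest.approx(1.0)

    n = 400
    big = pd.DataFrame({"gene": [f"G{i}" for i in range(n)], "drug": "D1",
                        "effect": rng.standard_normal(n), "statistic": 0.0,
                        "p": rng.random(n), "n_mut": 5, "n_wt": 5,
                        "defined": True})
    other = big.copy()
    other["effect"] = rng.standard_normal(n)
    conc = biomarker_concordance(_bh_adjust(big), _bh_adjust(other))
    assert abs(conc["effect_rho"]) < 2 / math.sqrt(n)


def test_concordance_requires_common_defined_pairs():
    df = pd.DataFrame({"gene": ["G1"], "drug": ["D1"], "effect": [np.nan],
                       "statistic": [np.nan], "p": [np.nan], "q": [np.nan],
                       "n_mut": [0], "n_wt": [5], "defined": [False]})
    with pytest.raises(PgxError):
        biomarker_concordance(df, df.copy())


def test_zero_flip_rate_designs_identical():
    params = SimulationParams(n_cell_lines=80, n_drugs=4, n_genes=10,
                              n_causal_pairs=5, mutation_flip_rate=0.0)
    tab = run_design_comparison(params, n_reps=5, seed=3, designs=("A", "B"))
    piv = tab.pivot(index="rep", columns="design_id", values="hit_kappa")
    delta = piv["B_SHARED_MUTATIONS"] - piv["A_INDEPENDENT"]
    assert delta.abs().max() == pytest.approx(0.0)


def test_design_comparison_deterministic(small_params):
    t1 = run_design_comparison(small_params, n_reps=3, seed=5, designs=("A",))
    t2 = run_design_comparison(small_params, n_reps=3, seed=5, designs=("A",))
    pd.testing.assert_frame_equal(t1, t2)
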