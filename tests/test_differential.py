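"""Ln-ratio computation, pooled spread, Group A/B classification and summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lfqdiff import (
    GlobalSpread,
    LnRatioSet,
    Tissue,
    UsageError,
    ValidationError,
    classify_groups,
    compute_ln_ratios,
    differential_union,
    global_spread,
    impute_zeros,
    passing_counts,
    threshold_summary,
)
from lfqdiff.differential import magnitude_fold_change

from conftest import build_table, random_table

CHOL, EACS = Tissue.CHOL, Tissue.EACS


def ratio_set(matrix, num=CHOL, den=EACS, n_exp=None):
    arr = np.asarray(matrix, dtype=float)
    n_exp = n_exp or arr.shape[1]
    return LnRatioSet(
        num, den,
        pd.DataFrame(arr, index=[f"P{i}" for i in range(arr.shape[0])],
                     columns=[f"E{j+1}" for j in range(n_exp)]),
    )


def spread_with_threshold(threshold, num=CHOL, den=EACS):
    sem = threshold / 2.0
    return GlobalSpread(num, den, sd_global=sem * math.sqrt(3), sem_global=sem,
                        threshold=threshold, n_proteins=2)


# ---------------------------------------------------------------------------
# ln-ratios
# ---------------------------------------------------------------------------

def test_ln_ratio_arithmetic_and_missing_rule():
    arr = np.full((1, 3, 5), 5.0)
    arr[0, :, 0] = 20.0            # CHOL = 20, EACS = 5 -> ln 4
    arr[0, 1, 0] = 0.0             # undetected in both tissues in E2
    arr[0, 1, 3] = 0.0
    table = impute_zeros(build_table(arr))
    rs = compute_ln_ratios(table, CHOL, EACS)
    row = rs.ratios.loc["P0000"]
    assert row["E1"] == pytest.approx(math.log(4.0))
    assert np.isnan(row["E2"])
    assert row.notna().sum() == 2


def test_ln_ratio_detected_in_one_tissue_uses_imputed_floor():
    arr = np.full((2, 1, 5), 10.0)
    arr[0, 0, 0] = 0.0  # CHOL undetected, EACS detected -> ratio defined vs floor
    table = impute_zeros(build_table(arr))  # floor = 30
    rs = compute_ln_ratios(table, CHOL, EACS)
    assert rs.ratios.loc["P0000", "E1"] == pytest.approx(math.log(30.0 / 10.0))


def test_ln_ratio_swap_negates(rng):
    table = impute_zeros(random_table(rng, dropout=0.2))
    fwd = compute_ln_ratios(table, CHOL, EACS).ratios.to_numpy()
    rev = compute_ln_ratios(table, EACS, CHOL).ratios.to_numpy()
    np.testing.assert_allclose(fwd, -rev, equal_nan=True)


def test_ln_ratio_same_tissue_is_usage_error(rng):
    table = impute_zeros(random_table(rng))
    with pytest.raises(UsageError):
        compute_ln_ratios(table, CHOL, CHOL)


def test_ln_ratio_requires_imputed_table(rng):
    table = random_table(rng, dropout=0.3)
    with pytest.raises(ValidationError, match="impute"):
        compute_ln_ratios(table, CHOL, EACS)


# ---------------------------------------------------------------------------
# global spread
# ---------------------------------------------------------------------------

def test_global_spread_hand_computed_example():
    rs = ratio_set([[0.1, -0.1, 0.0], [0.2, 0.2, 0.2]])
    sp = global_spread(rs)
    assert sp.sd_global == pytest.approx(math.sqrt(0.02 / 4), abs=1e-12)
    assert sp.sem_global == pytest.approx(math.sqrt(0.02 / 4) / math.sqrt(3))
    assert sp.threshold == pytest.approx(2 * sp.sem_global)


def test_global_spread_zero_when_replicates_identical():
    rs = ratio_set([[0.5, 0.5, 0.5], [-1.0, -1.0, -1.0]])
    assert global_spread(rs).sd_global == 0.0


def test_global_spread_matches_direct_formula(rng):
    R = rng.normal(0, 0.7, size=(40, 3))
    R[rng.random(R.shape) < 0.2] = np.nan
    R[:2] = 0.1  # guarantee >= 2 usable proteins
    sp = global_spread(ratio_set(R))
    ss = dof = 0.0
    for row in R:
        vals = row[~np.isnan(row)]
        if len(vals) >= 2:
            ss += ((vals - vals.mean()) ** 2).sum()
            dof += len(vals) - 1
    assert sp.sd_global == pytest.approx(math.sqrt(ss / dof), rel=1e-12)


def test_global_spread_insufficient_data():
    with pytest.raises(ValidationError):
        global_spread(ratio_set([[0.1, np.nan, np.nan], [0.2, 0.1, np.nan]]))


def test_global_spread_alternative_estimators(rng):
    R = rng.normal(0, 0.5, size=(30, 3))
    rs = ratio_set(R)
    assert global_spread(rs, "all_ratios").sd_global == pytest.approx(np.std(R, ddof=1))
    assert global_spread(rs, "mean_ratios").sd_global == pytest.approx(
        np.std(R.mean(axis=1), ddof=1)
    )
    with pytest.raises(UsageError):
        global_spread(rs, "bogus")


# ---------------------------------------------------------------------------
# Group A/B classification
# ---------------------------------------------------------------------------

def test_group_a_assignment_with_direct_t_probability():
    ratios = [math.log(3.0), math.log(3.2), math.log(2.8)]
    rs = ratio_set([ratios])
    res = classify_groups(rs, spread_with_threshold(math.log(2.0)))
    rec = res.loc["P0"]
    assert rec["group"] == "A"
    assert rec["direction"] == "up"
    assert rec["mean_lnFC"] == pytest.approx(1.0971, abs=1e-4)
    # p-value from the t distribution with 2 df, evaluated directly
    arr = np.array(ratios)
    t = arr.mean() / (arr.std(ddof=1) / math.sqrt(3))
    expected_p = 2 * (1 - stats.t.cdf(abs(t), df=2))
    assert rec["p_value"] == pytest.approx(expected_p, rel=1e-12)
    assert expected_p < 0.05


def test_group_b_two_replicates_consistent_sign():
    rs = ratio_set([[0.9, 1.4, np.nan]])
    res = classify_groups(rs, spread_with_threshold(0.693))
    assert res.loc["P0", "group"] == "B"
    assert res.loc["P0", "n_replicates"] == 2


def test_sign_disagreement_is_none():
    rs = ratio_set([[0.9, -1.4, 1.2]])
    res = classify_groups(rs, spread_with_threshold(0.693))
    assert res.loc["P0", "group"] == "none"


def test_magnitude_only_switch_admits_mixed_signs():
    rs = ratio_set([[0.9, -1.4, 1.2]])
    res = classify_groups(rs, spread_with_threshold(0.693), require_common_sign=False)
    assert res.loc["P0", "group"] == "B_triplicate"


def test_triplicate_b_label():
    rs = ratio_set([[0.9, 1.4, 1.2]])
    # mean exceeds threshold but p-value on 3 replicates misses 0.05 -> not A
    res = classify_groups(rs, spread_with_threshold(0.693), alpha=0.001)
    assert res.loc["P0", "group"] == "B_triplicate"


def test_group_a_tested_before_b():
    # passes both sets of rules; A wins
    rs = ratio_set([[1.0, 1.01, 0.99]])
    res = classify_groups(rs, spread_with_threshold(0.5))
    assert res.loc["P0", "group"] == "A"


def test_single_replicate_is_ineligible():
    rs = ratio_set([[2.0, np.nan, np.nan]])
    res = classify_groups(rs, spread_with_threshold(0.1))
    assert res.loc["P0", "group"] == "none"
    assert np.isnan(res.loc["P0", "p_value"])


def test_passing_magnitude_at_least_exp_threshold(rng):
    table = impute_zeros(random_table(rng, n_proteins=80, dropout=0.25))
    rs = compute_ln_ratios(table, CHOL, EACS)
    sp = global_spread(rs)
    res = classify_groups(rs, sp)
    passing = res[res["group"].isin(["A", "B", "B_triplicate"])]
    for fc in passing["fold_change"]:
        assert magnitude_fold_change(fc) >= math.exp(sp.threshold) - 1e-12


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def make_results(groups, fold_changes=None, directions=None):
    n = len(groups)
    fc = fold_changes or [2.0] * n
    return pd.DataFrame(
        {
            "n_replicates": [3] * n,
            "mean_lnFC": np.log(fc),
            "fold_change": fc,
            "p_value": [0.01] * n,
            "direction": directions or ["up"] * n,
            "group": groups,
        },
        index=[f"P{i}" for i in range(n)],
    )


def test_passing_counts_and_empty():
    res = make_results(["A", "A", "B", "B_triplicate", "none"])
    assert passing_counts(res) == {"A": 2, "B": 2, "total": 4}
    empty = make_results([])
    assert passing_counts(empty) == {"A": 0, "B": 0, "total": 0}


def test_threshold_summary_minimum_and_inversion():
    res = make_results(
        ["A", "A", "A", "B", "none"], fold_changes=[2.7, 3.1, 5.0, 0.25, 1.0]
    )
    summary = threshold_summary(res)
    assert summary["A"] == pytest.approx(2.7)
    assert summary["B"] == pytest.approx(4.0)  # FC 0.25 enters as magnitude 4
    assert math.isnan(threshold_summary(make_results(["none"]))["A"])


def test_differential_union():
    r1 = make_results(["A", "B", "none"])          # P0, P1 pass
    r2 = make_results(["none", "B_triplicate", "A"])  # P1, P2 pass
    results = {(CHOL, EACS): r1, (CHOL, Tissue.TYMP): r2,
               (Tissue.TYMP, Tissue.MUC): make_results(["A", "A", "A"])}
    union = differential_union(results, CHOL)
    assert union == {"P0", "P1", "P2"}
    assert differential_union({(CHOL, EACS): make_results(["none"])}, CHOL) == set()
    with pytest.raises(UsageError):
        differential_union({(Tissue.TYMP, Tissue.MUC): r1}, CHOL)


def test_spread_comparison_mismatch_rejected():
    rs = ratio_set([[0.1, 0.2, 0.3], [0.1, 0.1, 0.2]])
    wrong = spread_with_threshold(0.5, num=Tissue.TYMP, den=Tissue.MUC)
    with pytest.raises(UsageError):
        classify_groups(rs, wrong)
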