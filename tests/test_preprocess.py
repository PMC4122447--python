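"""Normalization, presence filtering, imputation and identification statistics."""

import numpy as np
import pytest

from lfqdiff import (
    Tissue,
    ValidationError,
    filter_by_experiment_presence,
    impute_zeros,
    normalize_equal_sum,
    overlap_summary,
    replicate_consistency,
)
from lfqdiff.preprocess import EqualSumNormalizer

from conftest import build_table, random_table


# ---------------------------------------------------------------------------
# equal-sum normalization
# ---------------------------------------------------------------------------

def test_normalize_two_samples_to_grand_mean():
    # sample sums 100 and 200 -> target 150 -> scale factors 1.5 and 0.75
    table = build_table(
        [[[40.0, 120.0]], [[60.0, 80.0]]], tissues=[Tissue.CHOL, Tissue.EACS]
    )
    norm = EqualSumNormalizer().fit(table)
    assert norm.scale_factors_[("E1", "CHOL")] == pytest.approx(1.5)
    assert norm.scale_factors_[("E1", "EACS")] == pytest.approx(0.75)
    out = norm.transform(table)
    assert out.values.sum(axis=0).tolist() == pytest.approx([150.0, 150.0])


def test_normalize_equal_sums_is_identity(rng):
    arr = rng.uniform(1, 10, size=(4, 2, 5))
    arr *= (100.0 / arr.sum(axis=0))[None, :, :]
    table = build_table(arr)
    out = normalize_equal_sum(table)
    np.testing.assert_allclose(out.values.to_numpy(), table.values.to_numpy())


def test_normalize_all_zero_sample_is_error():
    arr = np.ones((3, 1, 5))
    arr[:, 0, 2] = 0.0
    with pytest.raises(ValidationError, match="TYMP"):
        normalize_equal_sum(build_table(arr))


def test_normalize_properties_on_random_tables(rng):
    for _ in range(10):
        table = random_table(rng, n_proteins=25)
        out = normalize_equal_sum(table)
        sums = out.values.sum(axis=0).to_numpy()
        assert sums.max() / sums.min() - 1 <= 1e-9
        # within-sample ratios preserved: output = scale factor x input
        ratio = out.values.to_numpy() / np.where(
            table.values.to_numpy() == 0, np.nan, table.values.to_numpy()
        )
        per_sample = np.nanstd(ratio, axis=0)
        assert np.nanmax(per_sample) < 1e-12


# ---------------------------------------------------------------------------
# experiment-presence filter
# ---------------------------------------------------------------------------

def presence_fixture():
    arr = np.zeros((3, 3, 5))
    arr[0, 0, 0] = 5.0                      # P0: experiment 1 only
    arr[1, 0, 1] = 1.0
    arr[1, 2, 3] = 2.0                      # P1: experiments 1 and 3
    arr[2, :, 4] = 3.0                      # P2: all experiments
    return build_table(arr)


def test_filter_removes_single_experiment_proteins():
    table = presence_fixture()
    out = filter_by_experiment_presence(table, 2)
    assert list(out.accessions) == ["P0001", "P0002"]


def test_filter_min_one_is_identity():
    table = presence_fixture()
    out = filter_by_experiment_presence(table, 1)
    assert out == table


def test_filter_monotone_in_min_experiments(rng):
    table = random_table(rng, n_proteins=40, dropout=0.5)
    sizes = [filter_by_experiment_presence(table, k).n_proteins for k in (1, 2, 3)]
    assert sizes == sorted(sizes, reverse=True)


# ---------------------------------------------------------------------------
# detection-floor imputation
# ---------------------------------------------------------------------------

def test_impute_three_times_minimum():
    arr = np.full((2, 1, 5), 20.0)
    arr[0, 0, 0] = 5.0
    arr[0, 0, 1] = 0.0
    arr[1, 0, 2] = 0.0
    out = impute_zeros(build_table(arr))
    assert out.values.iloc[0, 1] == 15.0
    assert out.values.iloc[1, 2] == 15.0
    # positives untouched, detection mask preserved
    assert out.values.iloc[0, 0] == 5.0
    assert not out.detected.iloc[0, 1]


def test_impute_factor_one_uses_minimum_itself():
    arr = np.full((1, 1, 5), 7.0)
    arr[0, 0, 3] = 0.0
    out = impute_zeros(build_table(arr), factor=1.0)
    assert out.values.iloc[0, 3] == 7.0


def test_impute_without_zeros_is_identity(rng):
    table = random_table(rng, dropout=0.0)
    assert impute_zeros(table) == table


def test_impute_idempotent(rng):
    table = random_table(rng, dropout=0.3)
    once = impute_zeros(table)
    twice = impute_zeros(once)
    assert once == twice


def test_impute_all_zero_table_is_error():
    with pytest.raises(ValidationError):
        impute_zeros(build_table(np.zeros((2, 1, 5))))


def test_impute_per_experiment_scope():
    arr = np.full((2, 2, 5), 100.0)
    arr[0, 0, 0] = 10.0   # min of E1
    arr[0, 1, 0] = 40.0   # min of E2
    arr[1, 0, 1] = 0.0    # P1 undetected in NECK, both experiments
    arr[1, 1, 1] = 0.0
    out = impute_zeros(build_table(arr), scope="experiment")
    assert out.values.loc["P0001", ("E1", "NECK")] == 30.0
    assert out.values.loc["P0001", ("E2", "NECK")] == 120.0


# ---------------------------------------------------------------------------
# overlap + replicate consistency
# ---------------------------------------------------------------------------

def test_overlap_counts_enumerable_case():
    # experiments detect {a,b,c}, {b,c}, {c}
    arr = np.zeros((3, 3, 5))
    arr[0, 0, 0] = 1.0
    arr[1, 0, 0] = arr[1, 1, 0] = 1.0
    arr[2, :, 0] = 1.0
    s = overlap_summary(build_table(arr))
    assert (s.n_total, s.n_at_least_two, s.n_all) == (3, 2, 1)
    assert s.per_experiment == {"E1": 3, "E2": 2, "E3": 1}


def test_overlap_single_experiment_table():
    arr = np.zeros((3, 1, 5))
    arr[:2, 0, 1] = 4.0
    s = overlap_summary(build_table(arr))
    assert (s.n_total, s.n_at_least_two, s.n_all) == (2, 0, 0)


def test_overlap_invariant_under_permutations(rng):
    table = random_table(rng, n_proteins=30, dropout=0.4)
    perm = rng.permutation(table.n_proteins)
    shuffled = table.replace(
        values=table.values.iloc[perm],
        meta=table.meta.iloc[perm],
        detected=table.detected.iloc[perm],
    )
    exps = ["E3", "E1", "E2"]
    cols = [(e, t.value) for e in exps for t in table.tissues]
    swapped = table.replace(
        values=table.values[cols], detected=table.detected[cols]
    )
    for other in (shuffled, swapped):
        a, b = overlap_summary(table), overlap_summary(other)
        assert (a.n_total, a.n_at_least_two, a.n_all) == (b.n_total, b.n_at_least_two, b.n_all)


def test_replicate_consistency_saturated_is_100():
    table = build_table(np.ones((4, 3, 5)))
    pct, mean = replicate_consistency(table)
    assert all(v == 100.0 for v in pct.values())
    assert mean == 100.0


def test_replicate_consistency_matches_brute_force(rng):
    table = random_table(rng, n_proteins=60, dropout=0.35)
    pct, mean = replicate_consistency(table)

    # direct enumeration over the presence matrix
    det = table.detected
    pres = table.presence_by_experiment()
    core = [a for a in table.accessions if pres.loc[a].all()]
    expected = {}
    for tissue in table.tissues:
        num = den = 0
        for acc in core:
            flags = [det.loc[acc, (e, tissue.value)] for e in table.experiments]
            if any(flags):
                den += 1
                if all(flags):
                    num += 1
        expected[tissue] = 100.0 * num / den if den else float("nan")
    for tissue, value in expected.items():
        assert pct[tissue] == pytest.approx(value, nan_ok=True)
    defined = [v for v in expected.values() if v == v]
    assert mean == pytest.approx(np.mean(defined))


def test_replicate_consistency_empty_tissue_excluded_from_mean():
    arr = np.ones((3, 3, 5))
    arr[:, :, 4] = 0.0  # mucosa never detected
    pct, mean = replicate_consistency(build_table(arr))
    assert np.isnan(pct[Tissue.MUC])
    assert mean == 100.0
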